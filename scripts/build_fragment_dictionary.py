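"""Build the packaged FragFp fragment dictionary.

The dictionary is derived from a deterministic corpus: one generated
degradation set of 300 molecules for each of the three packaged seed drugs
(RNG seed 20240101).  Fragments are selected by match frequency under a
mutual match-pattern correlation cap; see
``extrapolab.descriptors.build_fragment_dictionary``.

Usage: python scripts/build_fragment_dictionary.py [--out PATH]
"""

import argparse
import time
from pathlib import Path

from extrapolab import molgen
from extrapolab.descriptors import build_fragment_dictionary
from extrapolab.molgen import DegradationConfig

CORPUS_SEED = 20240101
DEFAULT_OUT = Path(__file__).resolve().parent.parent / "src/extrapolab/data/fragfp_dictionary_v1.smarts"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=DEFAULT_OUT)
    parser.add_argument("--size", type=int, default=512)
    args = parser.parse_args()

    corpus = []
    for si, (name, seed_mol) in enumerate(molgen.seed_library()):
        cfg = DegradationConfig(target_set_size=300, seed=CORPUS_SEED + si)
        corpus.extend(molgen.generate_set(seed_mol, cfg, name, 1).molecules)
    print(f"corpus: {len(corpus)} molecules")
    t0 = time.time()
    dictionary = build_fragment_dictionary(
        corpus, size=args.size, corpus_id=f"degradation-union-seed{CORPUS_SEED}"
    )
    print(f"built {len(dictionary)} fragments in {time.time() - t0:.0f}s")
    dictionary.save(args.out)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
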