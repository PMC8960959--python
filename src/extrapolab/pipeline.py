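"""End-to-end orchestration: generate -> featurize -> respond -> run -> report.

The full factorial sweep — seed drugs x replicate sets x descriptors x
responses x orderings — yields 3*3*3*3*3 = 243 dataset cells per engine.
``run_all`` executes them deterministically under the configured seeds,
appending to a results CSV so interrupted sweeps resume where they stopped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import molgen, reporting
from .descriptors import DESCRIPTOR_KINDS, descriptor_matrix, load_default_dictionary
from .molgen import DegradationConfig, MoleculeSet, SEED_NAMES
from .regressors import normalize_engine
from .responses import RESPONSE_KINDS, compute_responses
from .successive import ORDERINGS, _derive_seed, order_dataset, run_successive

log = logging.getLogger(__name__)

DEFAULT_ENGINES = ("MEDIAN", "KNN", "PLS", "PLSP", "GPR")


@dataclass
class RunConfig:
    """Sweep configuration; everything is seeded (no wall-clock seeding)."""

    seed_names: tuple[str, ...] = SEED_NAMES
    replicates: int = 3
    set_size: int = 300
    max_steps: int = 30
    descriptors: tuple[str, ...] = DESCRIPTOR_KINDS
    responses: tuple[str, ...] = RESPONSE_KINDS
    orderings: tuple[str, ...] = ORDERINGS
    engines: tuple[str, ...] = DEFAULT_ENGINES
    grid_mode: str = "reduced"
    rng_seed: int = 7
    cv_splits: int = 11
    cv_holdout: float = 0.25
    out_dir: str = "extrapolab_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.engines = tuple(normalize_engine(e) for e in self.engines)
        for d in self.descriptors:
            if d not in DESCRIPTOR_KINDS:
                raise ValueError(f"unknown descriptor {d!r}")
        for r in self.responses:
            if r not in RESPONSE_KINDS:
                raise ValueError(f"unknown response {r!r}")
        self.orderings = tuple(o.upper() for o in self.orderings)
        for o in self.orderings:
            if o not in ORDERINGS:
                raise ValueError(f"unknown ordering {o!r}")

    @property
    def n_cells(self) -> int:
        return (
            len(self.seed_names)
            * self.replicates
            * len(self.descriptors)
            * len(self.responses)
            * len(self.orderings)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("seed_names", "descriptors", "responses", "orderings", "engines"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def generate_all_sets(cfg: RunConfig) -> dict[tuple[str, int], MoleculeSet]:
    """All replicate molecule sets for the configured seed drugs.

    Replicate RNG seeds are derived deterministically from the run seed and
    the seed drug's position in the packaged library.
    """
    library = dict(molgen.seed_library())
    out: dict[tuple[str, int], MoleculeSet] = {}
    for si, name in enumerate(cfg.seed_names):
        if name not in library:
            raise ValueError(f"unknown seed molecule {name!r}")
        base = DegradationConfig(
            target_set_size=cfg.set_size,
            max_steps_per_molecule=cfg.max_steps,
            seed=_derive_seed(cfg.rng_seed, si),
        )
        for rep_set in molgen.generate_replicates(library[name], base, name, cfg.replicates):
            out[(name, rep_set.replicate_index)] = rep_set
    return out


def _cell_key(seed_name: str, replicate: int, descriptor: str, response: str, ordering: str, engine: str) -> tuple:
    return (seed_name, int(replicate), descriptor, response, ordering, engine)


def run_all(cfg: RunConfig, results_path: str | Path | None = None) -> pd.DataFrame:
    """Execute the configured sweep; returns the long results table.

    If *results_path* exists, cells already present there are skipped and
    the file is extended in place (resumability); rerunning a completed
    sweep with the same config reproduces the file byte for byte.
    """
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if results_path is None:
        results_path = outdir / "results.csv"
    results_path = Path(results_path)
    done: set[tuple] = set()
    frames: list[pd.DataFrame] = []
    if results_path.exists():
        prev = pd.read_csv(results_path)
        if not prev.empty:
            frames.append(prev)
            done = {
                _cell_key(*row)
                for row in prev[reporting.CELL_AXES].drop_duplicates().itertuples(index=False)
            }
            log.info("resuming: %d cells already in %s", len(done), results_path)

    sets = generate_all_sets(cfg)
    dictionary = load_default_dictionary() if "FragFp" in cfg.descriptors else None
    n_new = 0
    for (seed_name, rep), mol_set in sets.items():
        resp_table = compute_responses(mol_set.molecules, cfg.responses)
        for di, desc in enumerate(cfg.descriptors):
            X = None  # featurize lazily: skip if every cell is done
            for ri, resp in enumerate(cfg.responses):
                for oi, ordering in enumerate(cfg.orderings):
                    cell_engines = [
                        e
                        for e in cfg.engines
                        if _cell_key(seed_name, rep, desc, resp, ordering, e) not in done
                    ]
                    if not cell_engines:
                        continue
                    if X is None:
                        X = descriptor_matrix(mol_set.molecules, desc, dictionary)
                    ds = order_dataset(
                        X,
                        resp_table[resp].to_numpy(),
                        ordering,
                        rng_seed=_derive_seed(cfg.rng_seed, 1 + rep, di, ri, oi),
                        meta={
                            "seed_name": seed_name,
                            "replicate": rep,
                            "descriptor": desc,
                            "response": resp,
                            "ordering": ordering,
                        },
                    )
                    for engine in cell_engines:
                        log.info(
                            "cell %s rep%d %s %s %s %s",
                            seed_name, rep, desc, resp, ordering, engine,
                        )
                        res = run_successive(
                            ds, engine, grid_mode=cfg.grid_mode,
                            splits=cfg.cv_splits, holdout=cfg.cv_holdout,
                        )
                        frame = reporting.results_to_frame([res])
                        frames.append(frame)
                        n_new += 1
                        combined = pd.concat(frames, ignore_index=True)
                        combined.to_csv(results_path, index=False)
    log.info("sweep complete: %d new cells, results in %s", n_new, results_path)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def report_all(results: pd.DataFrame, cfg: RunConfig, outdir: str | Path | None = None):
    meta = {
        "rng_seed": cfg.rng_seed,
        "grid_mode": cfg.grid_mode,
        "cv_splits": cfg.cv_splits,
        "cv_holdout": cfg.cv_holdout,
        "set_size": cfg.set_size,
        "engines": list(cfg.engines),
    }
    return reporting.write_report(results, outdir or Path(cfg.out_dir) / "report", meta)
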