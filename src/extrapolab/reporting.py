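"""Aggregation of successive-regression results into summary tables.

Two summaries are produced from the long results table (one row per cell and
train fraction):

* per-condition median relative errors over the molecule sets, laid out as
  engines x train-fraction columns (0.30..0.90 — the initial window's test
  block at train fraction 0.2 is computed but not tabulated);
* top-3 rank counts: within each ranked group, all (level, residual)
  error combinations are ranked ascending and each of the three lowest
  increments its level's count.  Ranking on counts rather than raw errors
  removes the systematic decrease of error with training fraction.

The ranked-group definition is configurable; the defaults give the
conservation laws column_sum = 3 x n_groups with 9 groups for the engine
summary and 21 for the descriptor and response summaries.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .successive import SuccessiveResult, TRAIN_FRACTIONS

log = logging.getLogger(__name__)

TABLE_FRACTIONS = TRAIN_FRACTIONS[1:]  # 0.3 .. 0.9, the tabulated columns

CELL_AXES = ["seed_name", "replicate", "descriptor", "response", "ordering", "engine"]

#: Default ranked-group axes per summary axis; the residual axes (everything
#: else except the set identity) vary within a group.
DEFAULT_RANK_GROUPING = {
    "engine": ("response", "descriptor"),
    "descriptor": ("response", "train_frac"),
    "response": ("descriptor", "engine"),
}


def results_to_frame(results: list[SuccessiveResult]) -> pd.DataFrame:
    """Flatten successive results into the long results table."""
    rows = []
    for res in results:
        for rec in res.records:
            row = dict(res.meta)
            row.update(
                engine=res.engine,
                train_frac=rec.train_frac,
                error=rec.error,
                cv_error=rec.cv_error,
                n_train=rec.n_train,
                n_test=rec.n_test,
                params=rec.spec.to_json(),
            )
            rows.append(row)
    return pd.DataFrame(rows)


def median_over_sets(df: pd.DataFrame) -> pd.DataFrame:
    """Elementwise median across molecule sets (seed x replicate) for every
    (descriptor, response, ordering, engine, train_frac) condition."""
    if df.empty:
        raise ValueError("empty results table")
    group_cols = ["descriptor", "response", "ordering", "engine", "train_frac"]
    counts = df.groupby(group_cols, dropna=False)["error"].count()
    expected = df.groupby(group_cols, dropna=False)[["seed_name", "replicate"]].nunique()
    n_sets = (expected["seed_name"] * expected["replicate"]).max()
    if (counts < n_sets).any():
        log.warning("some conditions have fewer than %d sets; median of available used", n_sets)
    med = df.groupby(group_cols, dropna=False)["error"].median().reset_index()
    return med


def table2_frame(
    medians: pd.DataFrame, descriptor: str, response: str, ordering: str
) -> pd.DataFrame:
    """Engines x train-fraction (0.30..0.90) matrix of median errors."""
    sub = medians[
        (medians.descriptor == descriptor)
        & (medians.response == response)
        & (medians.ordering == ordering)
        & (medians.train_frac.isin(TABLE_FRACTIONS))
    ]
    table = sub.pivot(index="engine", columns="train_frac", values="error")
    return table.sort_index()


def rank_counts(
    medians: pd.DataFrame,
    axis: str,
    grouping: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Top-3 rank counts per level of *axis*, one column per ordering.

    Within each ranked group (a combination of the *grouping* axes), all
    remaining (axis level x residual axes) error entries are ranked
    ascending; the levels owning the three lowest errors get +1 each.  Ties
    at third place all count.  Groups with fewer than 4 entries count every
    level, with a warning.
    """
    if axis not in ("engine", "descriptor", "response"):
        raise ValueError(f"axis must be engine/descriptor/response, got {axis!r}")
    if grouping is None:
        grouping = DEFAULT_RANK_GROUPING[axis]
    if axis in grouping:
        raise ValueError("the summary axis cannot be part of the grouping")
    levels = sorted(medians[axis].unique())
    orderings = [o for o in ("SHUFFLED", "LOW2HIGH", "HIGH2LOW") if o in set(medians.ordering)]
    out = pd.DataFrame(0, index=levels, columns=orderings)
    for ordering in orderings:
        sub = medians[(medians.ordering == ordering) & medians.train_frac.isin(TABLE_FRACTIONS)]
        for _, group in sub.groupby(list(grouping), dropna=False):
            entries = group[[axis, "error"]].dropna()
            if len(entries) < 4:
                log.warning("ranked group with %d entries: all levels counted", len(entries))
                for lv in entries[axis]:
                    out.loc[lv, ordering] += 1
                continue
            cutoff = np.sort(entries["error"].to_numpy())[2]
            top = entries[entries["error"] <= cutoff]
            for lv in top[axis]:
                out.loc[lv, ordering] += 1
    out.index.name = axis
    return out


def write_report(
    results: pd.DataFrame,
    outdir: str | Path,
    metadata: dict | None = None,
    rank_grouping: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, Path]:
    """Write medians CSVs (Table-2 shape per condition), rank-count CSVs and
    a run-metadata JSON.  Regenerating from the same results table is
    byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    medians = median_over_sets(results)
    p = outdir / "medians_long.csv"
    medians.to_csv(p, index=False)
    written["medians_long"] = p
    tables_dir = outdir / "tables"
    tables_dir.mkdir(exist_ok=True)
    combos = medians[["descriptor", "response", "ordering"]].drop_duplicates().sort_values(
        ["descriptor", "response", "ordering"]
    )
    for _, row in combos.iterrows():
        t = table2_frame(medians, row.descriptor, row.response, row.ordering)
        p = tables_dir / f"medians_{row.descriptor}_{row.response}_{row.ordering}.csv"
        t.to_csv(p)
        written[p.stem] = p
    grouping = dict(DEFAULT_RANK_GROUPING)
    grouping.update(rank_grouping or {})
    for axis in ("engine", "descriptor", "response"):
        try:
            rc = rank_counts(medians, axis, grouping[axis])
        except Exception as exc:
            log.warning("rank summary for %s skipped: %s", axis, exc)
            continue
        p = outdir / f"rank_counts_{axis}.csv"
        rc.to_csv(p)
        written[f"rank_counts_{axis}"] = p
    meta = dict(metadata or {})
    meta.setdefault("error_metric", "mean_abs_error / mean_abs_response")
    meta["rank_grouping"] = {k: list(v) for k, v in grouping.items()}
    p = outdir / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written["metadata"] = p
    return written


def plot_error_vs_fraction(
    results: pd.DataFrame,
    path: str | Path,
    response: str,
    ordering: str,
) -> None:
    """Error-vs-fraction scatter, coloured by engine, marker by descriptor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    medians = median_over_sets(results)
    sub = medians[(medians.response == response) & (medians.ordering == ordering)]
    markers = {"FragFp": "o", "PathFp": "s", "SkelSpheres": "^"}
    colors = {
        "MEDIAN": "green", "KNN": "red", "GPR": "blue", "PLS": "gold",
        "PLSP": "deepskyblue", "RFR": "magenta", "SVR": "orange",
    }
    fig, ax = plt.subplots(figsize=(6, 4))
    for (eng, desc), grp in sub.groupby(["engine", "descriptor"]):
        ax.scatter(
            grp.train_frac, grp.error,
            c=colors.get(eng, "gray"), marker=markers.get(desc, "x"),
            label=f"{eng}/{desc}", s=25,
        )
    ax.set_xlabel("fraction of training data")
    ax.set_ylabel("relative error")
    ax.set_title(f"{response}, {ordering}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
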