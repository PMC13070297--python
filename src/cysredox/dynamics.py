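"""Per-condition oxidation means, Δ oxidation and the dynamic/stable call.

A cysteine's reversible-oxidation stoichiometry is measured as a percentage
per (tissue × age) condition with replicates.  The dynamics of a site are
summarized by Δ = max − min of its condition means; a site is *dynamic* when
Δ strictly exceeds a threshold (default 10 percentage points) and *stable*
otherwise.  Sites observed in fewer than two conditions carry no contrast and
are reported as unclassifiable rather than stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 10.0

OXTABLE_COLUMNS = ["site_id", "protein", "position", "condition", "replicate", "pct_oxidation"]

FAMILIES = ["kinase", "phosphatase", "transcription factor", "metabolic enzyme"]


def validate_oxidation_table(table: pd.DataFrame) -> None:
    missing = [c for c in OXTABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"oxidation table missing columns {missing}")
    if table.empty:
        raise ValueError("empty oxidation table")
    vals = table["pct_oxidation"].to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        raise ValueError("pct_oxidation outside [0, 100]")
    dup = table.duplicated(subset=["site_id", "condition", "replicate"])
    if dup.any():
        raise ValueError("duplicate (site, condition, replicate) rows")


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean and s.e.m. of % oxidation over replicates.

    One row per observed (site, condition); conditions with no data are
    omitted, never imputed.  s.e.m. = sd(ddof=1)/sqrt(n) (NaN for n = 1).
    """
    validate_oxidation_table(table)
    g = table.groupby(["site_id", "protein", "position", "condition"], sort=True)[
        "pct_oxidation"
    ]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def delta_oxidation(means: pd.DataFrame) -> pd.DataFrame:
    """Δ oxidation (max − min of condition means) per site.

    Sites with fewer than two observed conditions get ``classifiable=False``
    and NaN delta.  Argmin/argmax condition labels and their means ± s.e.m.
    are carried for reporting.
    """
    rows = []
    for (site, protein, pos), sub in means.groupby(
        ["site_id", "protein", "position"], sort=True
    ):
        sub = sub.sort_values("condition").reset_index(drop=True)
        n_cond = len(sub)
        if n_cond < 2:
            rows.append(
                dict(
                    site_id=site, protein=protein, position=pos, delta=np.nan,
                    n_conditions=n_cond, classifiable=False,
                    min_condition=None, min_mean=np.nan, min_sem=np.nan,
                    max_condition=None, max_mean=np.nan, max_sem=np.nan,
                )
            )
            continue
        imin = int(sub["mean"].idxmin())
        imax = int(sub["mean"].idxmax())
        rows.append(
            dict(
                site_id=site, protein=protein, position=pos,
                delta=float(sub.loc[imax, "mean"] - sub.loc[imin, "mean"]),
                n_conditions=n_cond, classifiable=True,
                min_condition=sub.loc[imin, "condition"],
                min_mean=float(sub.loc[imin, "mean"]),
                min_sem=float(sub.loc[imin, "sem"]),
                max_condition=sub.loc[imax, "condition"],
                max_mean=float(sub.loc[imax, "mean"]),
                max_sem=float(sub.loc[imax, "sem"]),
            )
        )
    return pd.DataFrame(rows)


def classify(delta: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'dynamic' iff delta strictly exceeds the threshold, else 'stable'.

    The boundary is strict: delta == threshold is stable ("more than 10%").
    """
    if delta < 0:
        raise ValueError(f"negative delta {delta}")
    return "dynamic" if delta > threshold else "stable"


def classify_sites(
    table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Full per-site dynamics call from a replicate-level oxidation table.

    Convenience composition of :func:`condition_means`,
    :func:`delta_oxidation` and :func:`classify`; unclassifiable sites get
    ``klass='unclassifiable'``.
    """
    calls = delta_oxidation(condition_means(table))
    calls["klass"] = [
        classify(d, threshold) if ok else "unclassifiable"
        for d, ok in zip(calls["delta"], calls["classifiable"])
    ]
    return calls


def top_k_by_family(
    calls: pd.DataFrame, classes: pd.DataFrame, k: int = 10,
    families: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Top-k most dynamic sites per protein family.

    ``classes`` has columns (protein, family).  Sites are ranked by delta
    descending; ties broken lexicographically by site_id.  Each returned row
    carries the lowest- and highest-average condition with mean ± s.e.m.
    """
    if families is None:
        families = FAMILIES
    known = set(classes["family"].unique())
    for fam in families:
        if fam not in known:
            raise KeyError(f"unknown family {fam!r}")
    usable = calls[calls["classifiable"]].merge(classes, on="protein")
    out = {}
    for fam in families:
        sub = usable[usable["family"] == fam].sort_values(
            ["delta", "site_id"], ascending=[False, True]
        )
        out[fam] = sub.head(k).reset_index(drop=True)
    return out
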