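"""Competition-ratio scoring of covalent-compound engagement per cysteine.

In a TMT competition experiment, live cells are treated with vehicle (DMSO)
or compound; the compound blocks its target cysteine from subsequent
enrichment, depleting the treated channel's reporter signal-to-noise.  The
engagement score for a site is

    R = S/N(DMSO) / S/N(treated),

and the site-specific percent modification (covalent stoichiometry) is

    % modification = 100 * (1 - 1/R), clamped to [0, 100],

so R = 2 corresponds to 50% engagement.  Reproducibility is judged over all
DMSO-replicate x treated-replicate pairs: a site is a reproducible hit at a
dose when at least ``min_pair_fraction`` of pairwise R values exceed
``r_threshold``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SNTABLE_COLUMNS = ["site_id", "protein", "position", "channel", "treatment", "dose_uM", "replicate", "sn"]

DEFAULT_R_THRESHOLD = 2.0
DEFAULT_MIN_PAIR_FRACTION = 0.75


def validate_sn_table(table: pd.DataFrame) -> None:
    missing = [c for c in SNTABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"S/N table missing columns {missing}")
    if (table["sn"] <= 0).any():
        raise ValueError("S/N values must be > 0")
    if table.duplicated(subset=["site_id", "channel"]).any():
        raise ValueError("duplicate (site, channel) rows")


def engagement_ratio(sn_dmso: float, sn_treated: float) -> float:
    """R = S/N(DMSO) / S/N(treated)."""
    if sn_dmso <= 0 or sn_treated <= 0:
        raise ValueError("S/N inputs must be positive")
    return sn_dmso / sn_treated


def percent_modification(r: float) -> float:
    """100·(1 − 1/R), clamped to [0, 100].

    R < 1 (treated signal above DMSO, i.e. noise) clamps to 0: occupancy is
    physically non-negative.
    """
    if r <= 0:
        raise ValueError("R must be positive")
    return float(np.clip(100.0 * (1.0 - 1.0 / r), 0.0, 100.0))


def aggregate_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """Sum S/N across rows mapping to the same (site, channel).

    When a cysteine is quantified on several peptides, summation preserves
    the total reporter signal before ratio computation.
    """
    keys = ["site_id", "protein", "position", "channel", "treatment", "dose_uM", "replicate"]
    return table.groupby(keys, sort=True, as_index=False)["sn"].sum()


def score_engagement(table: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-arms R and % modification per site per dose.

    For each dose, R = mean S/N over DMSO channels / mean S/N over that
    dose's treated channels.  Returns one row per (site, dose).
    """
    validate_sn_table(table)
    rows = []
    for (site, protein, pos), g in table.groupby(["site_id", "protein", "position"], sort=True):
        dmso = g[g["treatment"] == "DMSO"]
        if dmso.empty:
            raise ValueError(f"{site}: no DMSO channels")
        sn_dmso = float(dmso["sn"].mean())
        for dose, gd in g[g["treatment"] != "DMSO"].groupby("dose_uM", sort=True):
            r = engagement_ratio(sn_dmso, float(gd["sn"].mean()))
            rows.append(
                dict(
                    site_id=site, protein=protein, position=pos, dose_uM=float(dose),
                    R=r, pct_modification=percent_modification(r),
                    n_pairs=len(dmso) * len(gd),
                )
            )
    return pd.DataFrame(rows)


def pairwise_replicate_R(table: pd.DataFrame, dose: float) -> pd.DataFrame:
    """All (DMSO replicate × treated replicate) R values per site at a dose.

    Returns a long DataFrame (site_id, dmso_replicate, treated_replicate, R)
    plus per-site ``R_median`` and ``R_iqr`` columns merged on.
    """
    validate_sn_table(table)
    dmso = table[table["treatment"] == "DMSO"].pivot(
        index="site_id", columns="replicate", values="sn"
    )
    trt = table[(table["treatment"] != "DMSO") & (table["dose_uM"] == dose)].pivot(
        index="site_id", columns="replicate", values="sn"
    )
    if dmso.empty or trt.empty:
        raise ValueError(f"missing arm at dose {dose}")
    sites = dmso.index.intersection(trt.index)
    missing = set(dmso.index).symmetric_difference(trt.index)
    if missing:
        raise ValueError(f"sites missing an arm at dose {dose}: {sorted(missing)[:5]}")
    if dmso.isna().any().any() or trt.isna().any().any():
        raise ValueError("ragged replicate structure; every site needs the same replicates")
    if dmso.shape[1] < 2 or trt.shape[1] < 2:
        raise ValueError("need >=2 replicates per arm")
    d = dmso.loc[sites].to_numpy(float)  # (n_sites, n_dmso)
    t = trt.loc[sites].to_numpy(float)  # (n_sites, n_trt)
    nd, nt = d.shape[1], t.shape[1]
    r = d[:, :, None] / t[:, None, :]  # (n_sites, nd, nt)
    out = pd.DataFrame(
        dict(
            site_id=np.repeat(sites.to_numpy(), nd * nt),
            dmso_replicate=np.tile(np.repeat(dmso.columns.to_numpy(), nt), len(sites)),
            treated_replicate=np.tile(np.tile(trt.columns.to_numpy(), nd), len(sites)),
            R=r.reshape(-1),
        )
    )
    stats = out.groupby("site_id")["R"].agg(
        R_median="median", R_iqr=lambda x: float(np.subtract(*np.percentile(x, [75, 25])))
    ).reset_index()
    return out.merge(stats, on="site_id")


def call_hits(
    pairwise: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_pair_fraction: float = DEFAULT_MIN_PAIR_FRACTION,
) -> pd.DataFrame:
    """Reproducible-hit calls from a pairwise-R table.

    A site is a reproducible hit when at least ``min_pair_fraction`` of its
    pairwise R values exceed ``r_threshold`` (R > 2 encodes the >50%
    engagement emphasis).
    """
    out = (
        pairwise.assign(above=pairwise["R"] > r_threshold)
        .groupby("site_id", sort=True)
        .agg(n_pairs=("R", "size"), fraction_above=("above", "mean"), R_median=("R", "median"))
        .reset_index()
    )
    out["hit"] = out["fraction_above"] >= min_pair_fraction
    return out


def selectivity_profile(
    scores: pd.DataFrame,
    target_site: str,
    paralog_protein: str | None = None,
) -> dict:
    """Dose-wise selectivity of a target site against the whole site table.

    For each dose: the target's % modification, its rank among all quantified
    sites (1 = highest), and the count of non-target sites exceeding it.
    Also returns per-cysteine tables for the target's protein and a named
    paralog.  A target absent from the table yields status "not quantified",
    never a silent zero.
    """
    if target_site not in set(scores["site_id"]):
        return {"status": "not quantified", "target_site": target_site}
    target_protein = scores.loc[scores["site_id"] == target_site, "protein"].iloc[0]
    per_dose = []
    for dose, g in scores.groupby("dose_uM", sort=True):
        tg = g[g["site_id"] == target_site]
        if tg.empty:
            per_dose.append(dict(dose_uM=float(dose), status="not quantified"))
            continue
        pct = float(tg["pct_modification"].iloc[0])
        others = g[g["site_id"] != target_site]
        n_exceed = int((others["pct_modification"] > pct).sum())
        per_dose.append(
            dict(
                dose_uM=float(dose), status="quantified",
                target_pct_modification=pct,
                rank=n_exceed + 1,
                n_exceeders=n_exceed,
            )
        )
    result = {
        "status": "quantified",
        "target_site": target_site,
        "target_protein": target_protein,
        "per_dose": per_dose,
        "target_protein_table": scores[scores["protein"] == target_protein].reset_index(drop=True),
    }
    if paralog_protein is not None:
        result["paralog_table"] = scores[scores["protein"] == paralog_protein].reset_index(drop=True)
    return result
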