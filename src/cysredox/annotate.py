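"""Functional annotation of classified cysteines and compendium assembly.

Domain intervals follow Pfam residue-coordinate conventions: 1-based,
inclusive at both ends.  Overlapping or nested domains are all reported — no
"primary" domain is chosen.  Protein-family labels (kinase, phosphatase,
transcription factor, metabolic enzyme) are a union over class tables, with
"other" when none match.  Structure identifiers are carried as opaque
strings.
"""

from __future__ import annotations

import pandas as pd

from .dynamics import FAMILIES


def validate_intervals(intervals: pd.DataFrame, protein_lengths: dict[str, int] | None = None) -> None:
    if (intervals["end"] < intervals["start"]).any():
        bad = intervals[intervals["end"] < intervals["start"]]
        raise ValueError(f"interval end < start for {bad['protein'].tolist()}")
    if (intervals["start"] < 1).any():
        raise ValueError("interval start < 1")
    if protein_lengths is not None:
        for _, row in intervals.iterrows():
            L = protein_lengths.get(row["protein"])
            if L is not None and row["end"] > L:
                raise ValueError(f"{row['protein']}: interval end {row['end']} > length {L}")


def map_to_domains(
    positions: pd.DataFrame,
    intervals: pd.DataFrame,
    protein_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Annotate (protein, position) rows with covering domain intervals.

    A position is in-domain iff start <= position <= end for some interval of
    the same protein (inclusive at both boundaries).  All covering domains
    are listed, sorted, semicolon-joined in ``domain_names``.
    """
    validate_intervals(intervals, protein_lengths)
    if protein_lengths is not None:
        for _, row in positions.iterrows():
            L = protein_lengths.get(row["protein"])
            if L is not None and row["position"] > L:
                raise ValueError(
                    f"{row['protein']} position {row['position']} exceeds length {L}"
                )
    by_protein = {p: g for p, g in intervals.groupby("protein")}
    in_domain = []
    names = []
    for _, row in positions.iterrows():
        g = by_protein.get(row["protein"])
        if g is None:
            covering = []
        else:
            hit = g[(g["start"] <= row["position"]) & (row["position"] <= g["end"])]
            covering = sorted(hit["domain_name"].tolist())
        in_domain.append(bool(covering))
        names.append(";".join(covering))
    out = positions.copy()
    out["in_domain"] = in_domain
    out["domain_names"] = names
    return out


def join_protein_classes(records: pd.DataFrame, class_table: pd.DataFrame) -> pd.DataFrame:
    """Attach family labels as the union of class memberships per protein.

    ``class_table`` has columns (protein, family); proteins matching no class
    are labeled "other".  Families are sorted, semicolon-joined.
    """
    fam_map: dict[str, list[str]] = {}
    if not class_table.empty:
        unknown = set(class_table["family"]) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown family labels {sorted(unknown)}")
        for prot, g in class_table.groupby("protein"):
            fam_map[prot] = sorted(set(g["family"]))
    out = records.copy()
    out["families"] = [";".join(fam_map.get(p, ["other"])) for p in out["protein"]]
    return out


def compile_compendium(
    dynamics_calls: pd.DataFrame,
    residue_maps: pd.DataFrame,
    intervals: pd.DataFrame,
    class_table: pd.DataFrame,
    structures: pd.DataFrame | None = None,
    protein_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One annotated record per conserved cysteine, plus summary fractions.

    Parameters
    ----------
    dynamics_calls : per-site output of :func:`cysredox.dynamics.classify_sites`
        keyed by (protein, position) on the mouse coordinate.
    residue_maps : DataFrame (protein, mouse_pos, human_pos) of conserved
        cysteines from the ortholog mapping stage.
    structures : optional DataFrame (protein, structure_id).

    Returns (records, summary); summary fractions are exact integer ratios.
    Duplicate (protein, position) rows on either join side are an error —
    never silently de-duplicated.
    """
    for name, df, keys in [
        ("dynamics", dynamics_calls, ["protein", "position"]),
        ("residue_maps", residue_maps, ["protein", "mouse_pos"]),
    ]:
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicate join keys in {name} input")

    rec = residue_maps.merge(
        dynamics_calls.rename(columns={"position": "mouse_pos"}),
        on=["protein", "mouse_pos"],
        how="left",
    )
    rec["klass"] = rec["klass"].fillna("unclassifiable")
    # domain membership evaluated on the human coordinate, matching the
    # annotation tables' species
    pos = rec[["protein", "human_pos"]].rename(columns={"human_pos": "position"})
    dom = map_to_domains(pos, intervals, protein_lengths)
    rec["in_domain"] = dom["in_domain"].to_numpy()
    rec["domain_names"] = dom["domain_names"].to_numpy()
    rec = join_protein_classes(rec, class_table)
    if structures is not None and not structures.empty:
        smap = {p: ";".join(sorted(g["structure_id"])) for p, g in structures.groupby("protein")}
    else:
        smap = {}
    rec["structure_ids"] = [smap.get(p, "") for p in rec["protein"]]

    n_total = len(rec)
    n_dynamic = int((rec["klass"] == "dynamic").sum())
    dyn = rec[rec["klass"] == "dynamic"]
    n_dyn_in_domain = int(dyn["in_domain"].sum())
    summary = {
        "n_conserved_cysteines": n_total,
        "n_dynamic": n_dynamic,
        "fraction_dynamic": n_dynamic / n_total if n_total else 0.0,
        "n_dynamic_in_domain": n_dyn_in_domain,
        "fraction_dynamic_in_domain": n_dyn_in_domain / n_dynamic if n_dynamic else 0.0,
    }
    cols = [
        "protein", "human_pos", "mouse_pos", "delta", "klass",
        "in_domain", "domain_names", "families", "structure_ids",
    ]
    return rec[cols], summary
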