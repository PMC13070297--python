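"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: mouse/human
ortholog sequence pairs with a known residue correspondence, multi-tissue
percent-oxidation tables with planted dynamic/stable sites, TMT competition
S/N tables with a known occupancy law, dose–response tables drawn from a
known 4PL, deconvoluted intact-MS species tables, and domain/class/structure
annotation tables.  Each generator returns its data together with a ground
truth object so downstream stages are testable without external downloads.

The stated world the defaults emulate: 10 tissues × 2 ages (20 conditions),
5 replicates per condition, ~6% of sites dynamically oxidized with a strict
>10 percentage-point threshold, a covalent agonist whose cellular occupancy
exceeds 50% between 10 and 20 μM, and an activation dose–response with
EC50 36.4 μM and maximal rate 14.2 pmol min⁻¹.

Determinism: every generator derives its RNG from ``(config.seed, stage)``,
so identical (seed, config) pairs produce byte-identical outputs and the
generators are independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ResidueMap, SequenceRecord
from .assays import FourPL

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CYS_FREQ = 0.04  # enriched over the sampling of other residues

# per-operation RNG stream tags
_STAGE = {
    "orthologs": 1, "oxidation": 2, "engagement": 3,
    "doseresponse": 4, "annotation": 5, "trace": 6,
}


@dataclass
class SyntheticConfig:
    """Knobs of the stated synthetic world (defaults are the emulated study design)."""

    seed: int = 0
    n_proteins: int = 20
    n_conditions: int = 20  # 10 tissues x 2 ages
    n_replicates: int = 5
    dynamic_fraction: float = 0.06
    noise_sd_oxidation: float = 2.0  # percentage points, replicate-level
    threshold: float = 10.0  # dynamic-call boundary, percentage points
    engagement_K: float = 8.0  # uM; occupancy 0.5 at this dose
    engagement_hill: float = 1.5
    sn_base: float = 100.0
    activation_params: FourPL = field(
        default_factory=lambda: FourPL(bottom=1.0, top=14.2, ec50=36.4, hill=1.0)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.dynamic_fraction <= 1.0:
            raise ValueError("dynamic_fraction must be in [0,1]")
        if self.n_conditions < 2 or self.n_replicates < 1:
            raise ValueError("need >=2 conditions and >=1 replicate")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])


def condition_labels(n: int) -> list[str]:
    """Tissue x age labels when n is even, generic condition labels otherwise."""
    if n % 2 == 0:
        tissues = [f"T{t + 1:02d}" for t in range(n // 2)]
        return [f"{t}_{age}" for t in tissues for age in ("young", "old")]
    return [f"C{i + 1:02d}" for i in range(n)]


def hill_occupancy(dose, k: float, h: float):
    """Fractional occupancy d^h / (d^h + K^h) of a covalent site at dose d."""
    d = np.asarray(dose, dtype=float)
    return d**h / (d**h + k**h)


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=size))


# ---------------------------------------------------------------------------
# Ortholog sequence pairs


@dataclass
class OrthologPairTruth:
    protein: str
    residue_map: ResidueMap  # mouse -> human over all non-deleted residues
    conserved_cys: list[tuple[int, int]]  # (mouse_pos, human_pos), both C
    lost_cys: list[int]  # mouse C substituted or deleted in human
    identity: float


@dataclass
class OrthologPair:
    mouse: SequenceRecord
    human: SequenceRecord
    truth: OrthologPairTruth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    others = [a for a in AMINO_ACIDS if a != "C"]
    p = np.full(len(AMINO_ACIDS), (1.0 - _CYS_FREQ) / len(others))
    p[AMINO_ACIDS.index("C")] = _CYS_FREQ
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=p))


def gen_ortholog_pairs(
    config: SyntheticConfig,
    sub_rate: float = 0.05,
    indel_rate: float = 0.01,
    min_length: int = 50,
    max_length: int = 600,
) -> list[OrthologPair]:
    """Mouse sequences and mutated "human" copies with a known residue map.

    Point substitutions occur at ``sub_rate`` (always to a different
    residue); insertions and deletions of length 1–5 each occur at
    ``indel_rate / 2`` per residue.  Rates above 0.1 / 0.02 (which would push
    identity toward unidentifiable territory) are rejected, as is any
    realized pair below 40% identity.
    """
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if sub_rate > 0.1:
        raise ValueError("substitution rate above 0.1 rejected (identity would be unreliable)")
    if indel_rate > 0.02:
        raise ValueError("indel rate above 0.02 rejected")
    rng = config.rng("orthologs")
    pairs = []
    for i in range(config.n_proteins):
        name = f"PROT{i + 1:03d}"
        length = int(rng.integers(min_length, max_length + 1))
        mouse_seq = _random_sequence(rng, length)
        human_chars: list[str] = []
        map_pairs: list[tuple[int, int]] = []
        conserved: list[tuple[int, int]] = []
        lost: list[int] = []
        n_ident = 0
        for mpos, res in enumerate(mouse_seq, start=1):
            if rng.random() < indel_rate / 2.0:  # insertion into human
                ins_len = int(rng.integers(1, 6))
                human_chars.extend(_random_sequence(rng, ins_len))
            if rng.random() < indel_rate / 2.0:  # deletion from human
                if res == "C":
                    lost.append(mpos)
                continue
            if rng.random() < sub_rate:
                choices = [a for a in AMINO_ACIDS if a != res]
                new = str(rng.choice(choices))
                human_chars.append(new)
                map_pairs.append((mpos, len(human_chars)))
                if res == "C":
                    lost.append(mpos)
            else:
                human_chars.append(res)
                map_pairs.append((mpos, len(human_chars)))
                n_ident += 1
                if res == "C":
                    conserved.append((mpos, len(human_chars)))
        human_seq = "".join(human_chars)
        if not human_seq:
            human_seq = mouse_seq  # degenerate draw; fall back to identity
            map_pairs = [(p, p) for p in range(1, length + 1)]
            conserved = [(p, p) for p, r in enumerate(mouse_seq, 1) if r == "C"]
            lost, n_ident = [], length
        identity = n_ident / max(length, len(human_seq))
        if identity < 0.40:
            raise ValueError(f"{name}: realized identity {identity:.2f} < 0.40")
        pairs.append(
            OrthologPair(
                mouse=SequenceRecord(name, "mouse", mouse_seq),
                human=SequenceRecord(name, "human", human_seq),
                truth=OrthologPairTruth(name, ResidueMap(map_pairs), conserved, lost, identity),
            )
        )
    return pairs


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}|{rec.species}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_fasta(path) -> list[SequenceRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pid, species = rec.id.split("|")
        out.append(SequenceRecord(pid, species, str(rec.seq)))
    return out


# ---------------------------------------------------------------------------
# Oxidation tables


def gen_oxidation_table(
    config: SyntheticConfig,
    sites: list[tuple[str, str, int]],
) -> tuple[pd.DataFrame, dict]:
    """Replicate-level % oxidation across conditions with planted dynamics.

    ``sites`` is a list of (site_id, protein, position).  Exactly
    ``round(dynamic_fraction * n_sites)`` sites are planted dynamic with true
    Δ ≥ threshold + 3·noise_sd; the rest are stable with true Δ ≤ threshold −
    3·noise_sd.  Replicate values are condition mean + Gaussian noise,
    clipped to [0, 100].

    Returns (table, truth) where truth holds per-site class/Δ and the exact
    planted condition means.
    """
    if config.n_replicates < 2:
        raise ValueError("need >=2 replicates")
    rng = config.rng("oxidation")
    conds = condition_labels(config.n_conditions)
    n_sites = len(sites)
    n_dynamic = int(round(config.dynamic_fraction * n_sites))
    order = rng.permutation(n_sites)
    dynamic_idx = set(order[:n_dynamic].tolist())

    margin = 3.0 * config.noise_sd_oxidation
    hi_delta = (config.threshold + margin, min(60.0, config.threshold + margin + 40.0))
    lo_delta = (0.0, max(config.threshold - margin, 0.0))

    truth_rows, mean_rows, table_rows = [], [], []
    for i, (site_id, protein, position) in enumerate(sites):
        dynamic = i in dynamic_idx
        lo, hi = hi_delta if dynamic else lo_delta
        delta = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        center = float(rng.uniform(delta / 2.0 + 2.0, 98.0 - delta / 2.0))
        means = rng.uniform(center - delta / 2.0, center + delta / 2.0, size=len(conds))
        # pin the extremes so max-min equals the planted delta exactly
        jmin, jmax = rng.choice(len(conds), size=2, replace=False)
        means[jmin] = center - delta / 2.0
        means[jmax] = center + delta / 2.0
        truth_rows.append(
            dict(site_id=site_id, true_class="dynamic" if dynamic else "stable",
                 true_delta=delta,
                 true_min_condition=conds[jmin], true_max_condition=conds[jmax])
        )
        for c, mu in zip(conds, means):
            mean_rows.append(dict(site_id=site_id, condition=c, true_mean=float(mu)))
            noise = rng.normal(0.0, config.noise_sd_oxidation, size=config.n_replicates)
            vals = np.clip(mu + noise, 0.0, 100.0)
            for r, v in enumerate(vals, start=1):
                table_rows.append(
                    dict(site_id=site_id, protein=protein, position=position,
                         condition=c, replicate=r, pct_oxidation=float(v))
                )
    table = pd.DataFrame(table_rows)
    truth = {
        "sites": pd.DataFrame(truth_rows),
        "condition_means": pd.DataFrame(mean_rows),
    }
    return table, truth


# ---------------------------------------------------------------------------
# Chemoproteomic competition datasets


def gen_engagement_dataset(
    config: SyntheticConfig,
    doses: list[float],
    target_site: tuple[str, str, int],
    n_sites: int = 100,
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    off_target_site: tuple[str, str, int] | None = None,
    off_target_occupancy: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Competition S/N table with a planted engaged target site.

    The target's occupancy at dose d follows the Hill law
    d^h / (d^h + K^h) with (K, h) = (engagement_K, engagement_hill); treated
    S/N = DMSO-arm S/N × (1 − occupancy) × multiplicative lognormal noise of
    the given CV.  All other sites have occupancy 0, except an optional
    planted off-target engaged only at the top dose (the
    high-concentration-only off-target scenario).

    Returns (sn_table, truth) with truth rows (site_id, dose_uM,
    true_occupancy).
    """
    doses = [float(d) for d in doses]
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    if n_replicates < 2:
        raise ValueError("need >=2 replicates per arm")
    rng = config.rng("engagement")
    site_list = [tuple(target_site)]
    if off_target_site is not None:
        site_list.append(tuple(off_target_site))
    n_fill = n_sites - len(site_list)
    for i in range(n_fill):
        site_list.append((f"S{i + 1:05d}", f"BG{i % max(n_fill // 3, 1) + 1:03d}", 10 + i))

    top_dose = max(doses)
    rows, truth_rows = [], []
    for site_id, protein, position in site_list:
        base = config.sn_base * float(rng.lognormal(0.0, 0.5))
        dmso_vals = base * _mean_one_lognormal(rng, noise_cv, n_replicates)
        for r, v in enumerate(dmso_vals, start=1):
            rows.append(dict(site_id=site_id, protein=protein, position=position,
                             channel=f"DMSO_r{r}", treatment="DMSO", dose_uM=0.0,
                             replicate=r, sn=float(v)))
        for dose in doses:
            if site_id == target_site[0]:
                occ = float(hill_occupancy(dose, config.engagement_K, config.engagement_hill))
            elif off_target_site is not None and site_id == off_target_site[0] and dose == top_dose:
                occ = off_target_occupancy
            else:
                occ = 0.0
            truth_rows.append(dict(site_id=site_id, dose_uM=dose, true_occupancy=occ))
            remain = max(1.0 - occ, 1e-3)  # S/N stays positive even at full occupancy
            vals = base * remain * _mean_one_lognormal(rng, noise_cv, n_replicates)
            for r, v in enumerate(vals, start=1):
                rows.append(dict(site_id=site_id, protein=protein, position=position,
                                 channel=f"d{dose:g}_r{r}", treatment="compound",
                                 dose_uM=dose, replicate=r, sn=float(v)))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Activity dose-response


def gen_activity_doseresponse(
    config: SyntheticConfig,
    n_points: int = 10,
    noise_cv: float = 0.02,
    n_replicates: int = 4,
    doses: np.ndarray | None = None,
) -> tuple[pd.DataFrame, FourPL]:
    """Enzyme-activation rates drawn from the default 4PL with CV noise.

    Doses default to ``n_points`` log-spaced values spanning more than two
    decades bracketing the true EC50.  Responses are
    4PL(dose) × lognormal(CV).  Returns (table, truth 4PL).
    """
    truth = config.activation_params
    if doses is None:
        if n_points < 6:
            raise ValueError("need >=6 dose points spanning >=2 decades")
        doses = np.geomspace(truth.ec50 / 30.0, truth.ec50 * 30.0, n_points)
    doses = np.asarray(doses, dtype=float)
    rng = config.rng("doseresponse")
    rows = []
    for d in doses:
        y0 = float(truth(d))
        vals = y0 * _mean_one_lognormal(rng, noise_cv, n_replicates)
        for r, v in enumerate(vals, start=1):
            rows.append(dict(dose_uM=float(d), replicate=r, response=float(v)))
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Intact-MS species tables

SHP1_BASE_MASS_DA = 67561.0  # synthetic stand-in for a ~68 kDa phosphatase
ADDUCT_MASS_DA = 421.5  # synthetic covalent-adduct mass


def gen_intactms_species(
    fractions: list[float],
    base_mass: float = SHP1_BASE_MASS_DA,
    adduct_mass: float = ADDUCT_MASS_DA,
    total_intensity: float = 1e6,
) -> pd.DataFrame:
    """Deconvoluted intact-MS species table from adduct-count fractions.

    ``fractions[k]`` is the molecular fraction carrying k adducts; they must
    be non-negative and sum to 1 within 1e-9.  Masses are
    base_mass + k·adduct_mass; intensities are proportional to fractions.
    """
    frac = np.asarray(fractions, dtype=float)
    if np.any(frac < 0):
        raise ValueError("negative fraction")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {frac.sum()}, not 1")
    return pd.DataFrame(
        dict(
            mass_da=[base_mass + k * adduct_mass for k in range(len(frac))],
            intensity=frac * total_intensity,
            n_adducts=list(range(len(frac))),
        )
    )


# ---------------------------------------------------------------------------
# Kinetic traces (DiFMU)


def gen_kinetic_trace(
    config: SyntheticConfig,
    rate_pmol_min: float,
    au_per_pmol: float = 2.0,
    duration_min: float = 10.0,
    dt_min: float = 0.5,
    noise_sd_au: float = 0.0,
) -> pd.DataFrame:
    """Linear fluorescence trace at a known product-formation rate."""
    rng = config.rng("trace")
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    f = rate_pmol_min * au_per_pmol * t + rng.normal(0.0, noise_sd_au, size=len(t))
    return pd.DataFrame(dict(time_min=t, fluorescence=f))


# ---------------------------------------------------------------------------
# Annotation tables


def gen_annotation_tables(
    config: SyntheticConfig,
    protein_lengths: dict[str, int],
    sites: list[tuple[str, str, int]],
    in_domain_fraction: float = 0.95,
) -> dict:
    """Domain intervals, protein-class and structure tables with truth.

    Exactly ``round(in_domain_fraction * n_sites)`` sites are planted inside
    a domain interval (1-based inclusive); intervals never cover a site
    planted outside.  Each protein draws zero or more family memberships and
    zero to two structure identifiers.

    Returns dict with keys domains, classes, structures (DataFrames) and
    truth (site_id, in_domain).
    """
    from .dynamics import FAMILIES

    rng = config.rng("annotation")
    n_in = int(round(in_domain_fraction * len(sites)))
    order = rng.permutation(len(sites))
    chosen = set(order[:n_in].tolist())

    # positions that must stay uncovered, per protein
    excluded: dict[str, list[int]] = {}
    for i, (sid, prot, pos) in enumerate(sites):
        if i not in chosen:
            excluded.setdefault(prot, []).append(pos)

    domain_rows, truth_rows = [], []
    dom_counter = 0
    for i, (sid, prot, pos) in enumerate(sites):
        in_dom = i in chosen
        truth_rows.append(dict(site_id=sid, in_domain=in_dom))
        if not in_dom:
            continue
        L = protein_lengths.get(prot)
        if L is None:
            raise ValueError(f"unknown protein length for {prot}")
        if pos > L:
            raise ValueError(f"{sid}: position {pos} exceeds length {L}")
        left = int(rng.integers(0, 25))
        right = int(rng.integers(0, 25))
        start = max(1, pos - left)
        end = min(L, pos + right)
        for other in excluded.get(prot, []):
            if other < pos:
                start = max(start, other + 1)
            elif other > pos:
                end = min(end, other - 1)
        dom_counter += 1
        domain_rows.append(
            dict(protein=prot, start=start, end=end, domain_name=f"DOM{dom_counter:04d}")
        )

    class_rows = []
    for prot in sorted(protein_lengths):
        u = rng.random()
        if u < 0.25:
            fams = []
        elif u < 0.85:
            fams = [str(rng.choice(FAMILIES))]
        else:
            fams = list(rng.choice(FAMILIES, size=2, replace=False))
        for fam in fams:
            class_rows.append(dict(protein=prot, family=fam))

    struct_rows = []
    for j, prot in enumerate(sorted(protein_lengths)):
        n_struct = int(rng.integers(0, 3))
        for s in range(n_struct):
            kind = "AF" if s == 0 else "PDB"
            struct_rows.append(dict(protein=prot, structure_id=f"{kind}-{j + 1:04d}{s}"))

    return {
        "domains": pd.DataFrame(domain_rows, columns=["protein", "start", "end", "domain_name"]),
        "classes": pd.DataFrame(class_rows, columns=["protein", "family"]),
        "structures": pd.DataFrame(struct_rows, columns=["protein", "structure_id"]),
        "truth": pd.DataFrame(truth_rows),
    }
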