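"""Downstream biochemical quantitation.

Covers the quantitative assays used to characterize a covalent agonist after
chemoproteomic discovery:

* phosphatase kinetics — fluorogenic DiFMUP turnover converted to pmol
  phosphate released per minute via a linear DiFMU standard curve (1 pmol
  DiFMU ≡ 1 pmol phosphate);
* four-parameter logistic (4PL) dose–response fits for activation
  (EC50/Vmax) and inhibition (IC50);
* intact-mass labeling stoichiometry from deconvoluted species tables;
* fluorescence-polarization binding with normalization and a
  bootstrap-based "did the IC50 shift" comparison;
* ELISA 4PL standard-curve intrapolation;
* ΔΔCt qPCR fold changes; and phagocytosis % activity.

The 4PL is parameterized as

    y = bottom + (top - bottom) / (1 + (ec50 / x)^hill)        (activation)
    y = bottom + (top - bottom) / (1 + (x / ec50)^hill)        (inhibition)

fitted by bounded least squares on log10(dose) with a fixed initialization
rule (bottom/top from response extrema, ec50 from the dose bracketing the
half-range, hill = 1), so fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    """Raised when a curve fit fails to converge; carries diagnostics."""


# ---------------------------------------------------------------------------
# 4PL dose-response


@dataclass
class FourPL:
    """Four-parameter logistic curve.

    ``top`` doubles as Vmax for activation fits (rate units); ``ec50`` is the
    IC50 for inhibition fits.  Concentrations are on the linear scale (μM).
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    direction: str = "activation"

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.direction not in ("activation", "inhibition"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.direction == "activation":
            ratio = (self.ec50 / x) ** self.hill
        else:
            ratio = (x / self.ec50) ** self.hill
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio)


@dataclass
class DoseResponseFit:
    params: FourPL
    residual_norm: float
    converged: bool
    n_points: int
    message: str = ""

    @property
    def ec50(self) -> float:
        return self.params.ec50

    @property
    def vmax(self) -> float:
        return self.params.top


def _4pl_predict(theta, logx, direction):
    bottom, top, log_ec50, hill = theta
    if direction == "activation":
        ratio = 10.0 ** ((log_ec50 - logx) * hill)
    else:
        ratio = 10.0 ** ((logx - log_ec50) * hill)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_4pl(
    dose,
    response,
    direction: str = "activation",
    bottom_fixed: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit with a deterministic initialization rule.

    Parameters
    ----------
    dose, response : array-like, equal length; doses > 0, >=5 distinct doses.
    direction : "activation" (rising with dose) or "inhibition" (falling).
    bottom_fixed : pin the bottom asymptote (e.g. 1.0 on a fold-change
        scale); when None the bottom is free.

    Raises :class:`FitError` on non-convergence, never returning silent
    defaults.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if dose.shape != response.shape:
        raise ValueError("dose and response length mismatch")
    if np.any(dose <= 0):
        raise ValueError("doses must be positive")
    if not np.all(np.isfinite(response)):
        raise ValueError("responses must be finite")
    if len(np.unique(dose)) < 5:
        raise ValueError("need >=5 distinct doses")
    logx = np.log10(dose)

    lo, hi = float(response.min()), float(response.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    # initial ec50: dose whose mean response is nearest the half-range
    order = np.argsort(logx)
    half = (lo + hi) / 2.0
    idx = int(np.argmin(np.abs(response[order] - half)))
    log_ec50_0 = float(logx[order][idx])
    b0 = lo if direction == "activation" else hi
    t0 = hi if direction == "activation" else lo
    if bottom_fixed is not None:
        b0 = bottom_fixed

    lx_min, lx_max = logx.min() - 2.0, logx.max() + 2.0

    if bottom_fixed is None:
        theta0 = np.array([b0, t0, log_ec50_0, 1.0])
        lower = [lo - 2 * span, lo - 2 * span, lx_min, 0.05]
        upper = [hi + 2 * span, hi + 2 * span, lx_max, 10.0]

        def resid(theta):
            return _4pl_predict(theta, logx, direction) - response
    else:
        theta0 = np.array([t0, log_ec50_0, 1.0])
        lower = [lo - 2 * span, lx_min, 0.05]
        upper = [hi + 2 * span, lx_max, 10.0]

        def resid(theta):
            full = np.array([bottom_fixed, *theta])
            return _4pl_predict(full, logx, direction) - response

    res = optimize.least_squares(resid, theta0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise FitError(f"4PL fit did not converge: {res.message} (status {res.status})")
    if bottom_fixed is None:
        bottom, top, log_ec50, hill = res.x
    else:
        bottom = bottom_fixed
        top, log_ec50, hill = res.x
    params = FourPL(float(bottom), float(top), float(10.0 ** log_ec50), float(hill), direction)
    return DoseResponseFit(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=True,
        n_points=len(dose),
        message=res.message,
    )


# ---------------------------------------------------------------------------
# DiFMU standard curve and kinetic rates


@dataclass
class LinearStandardCurve:
    """Linear fluorescence-vs-quantity standard (AU per pmol DiFMU)."""

    slope: float  # AU per pmol
    intercept: float
    r_squared: float

    def signal_to_pmol(self, signal):
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


def fit_difmu_standard(pmol, signal, min_r_squared: float = 0.98) -> LinearStandardCurve:
    """Least-squares line through DiFMU standards; rejects poor linearity."""
    pmol = np.asarray(pmol, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(pmol) < 3:
        raise ValueError("need >=3 standards")
    fit = stats.linregress(pmol, signal)
    if fit.slope <= 0:
        raise ValueError("standard curve not monotone increasing")
    r2 = fit.rvalue**2
    if r2 < min_r_squared:
        raise ValueError(f"standard curve R²={r2:.4f} below {min_r_squared}")
    return LinearStandardCurve(float(fit.slope), float(fit.intercept), float(r2))


def difmu_rate(
    time_min,
    fluorescence,
    curve: LinearStandardCurve,
    window: tuple[float, float] | None = None,
) -> float:
    """Initial rate in pmol phosphate min⁻¹ from a kinetic trace.

    The least-squares slope of fluorescence vs time over ``window`` (default:
    the first 10 minutes) is converted via the DiFMU standard curve; turnover
    of 1 pmol DiFMU releases 1 pmol phosphate.
    """
    t = np.asarray(time_min, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if window is None:
        window = (t[0], t[0] + 10.0)
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise ValueError("window covers fewer than 3 points")
    slope_au = stats.linregress(t[mask], f[mask]).slope  # AU / min
    return float(slope_au / curve.slope)  # pmol / min


# ---------------------------------------------------------------------------
# Intact-MS labeling stoichiometry


def intact_percent_engagement(species) -> float:
    """Percent of protein molecules carrying >=1 covalent adduct.

    ``species`` is a DataFrame with columns (mass_da, intensity, n_adducts)
    including the unmodified (n_adducts = 0) species row, possibly at zero
    intensity.  Engagement = 100 · Σ intensity(n_adducts >= 1) / Σ intensity.
    Uniform labeling (all signal in adducted species) gives exactly 100.
    """
    inten = np.asarray(species["intensity"], dtype=float)
    nad = np.asarray(species["n_adducts"], dtype=int)
    if np.any(inten < 0):
        raise ValueError("negative intensity")
    total = inten.sum()
    if total == 0:
        raise ValueError("all-zero intensities")
    if 0 not in set(nad.tolist()):
        raise ValueError("species table must include the unmodified (n_adducts=0) row")
    return float(100.0 * inten[nad >= 1].sum() / total)


def species_percentages(species) -> dict[int, float]:
    """Percent of total intensity per adduct count (sums to 100)."""
    inten = np.asarray(species["intensity"], dtype=float)
    nad = np.asarray(species["n_adducts"], dtype=int)
    total = inten.sum()
    out: dict[int, float] = {}
    for k in sorted(set(nad.tolist())):
        out[int(k)] = float(100.0 * inten[nad == k].sum() / total)
    return out


# ---------------------------------------------------------------------------
# Fluorescence polarization


def fp_normalize_and_fit(
    concentration,
    mp,
    reference_concentration: float,
    mode: str = "saturation",
    mp_with_ligand=None,
    n_bootstrap: int = 200,
    seed: int = 0,
):
    """Normalize mP to a reference condition and fit binding curves.

    mP values are divided by the mean mP at ``reference_concentration`` (the
    stated normalization condition).  Binding is fit with the 4PL; for
    ``mode="saturation"`` the signal rises with protein concentration, for
    ``mode="competition"`` it falls with competitor concentration and the
    fitted midpoint is the IC50.

    When ``mp_with_ligand`` is given (same concentration grid), both curves
    are fitted and the ratio of IC50s is reported with a residual-bootstrap
    95% interval; ``changed`` is False when the interval covers 1 — the
    "no change on pre-incubation" comparison.
    """
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    mp = np.asarray(mp, dtype=float)
    ref_mask = np.isclose(conc, reference_concentration)
    if not ref_mask.any():
        raise ValueError(f"reference concentration {reference_concentration} absent")
    direction = "activation" if mode == "saturation" else "inhibition"

    def _fit(y):
        y_norm = y / np.mean(y[ref_mask])
        return fit_4pl(conc, y_norm, direction=direction), y_norm

    fit_a, _ = _fit(mp)
    result = {"fit": fit_a, "ic50": fit_a.ec50}
    if mp_with_ligand is None:
        return result

    fit_b, _ = _fit(np.asarray(mp_with_ligand, dtype=float))
    ratio = fit_b.ec50 / fit_a.ec50
    rng = np.random.default_rng(seed)

    def _boot(fit, y_norm):
        pred = fit.params(conc)
        resid = y_norm - pred
        out = []
        for _ in range(n_bootstrap):
            y_star = pred + rng.choice(resid, size=len(resid), replace=True)
            try:
                out.append(fit_4pl(conc, y_star, direction=direction).ec50)
            except (FitError, ValueError):
                continue
        return np.asarray(out)

    _, y_a = _fit(mp)
    _, y_b = _fit(np.asarray(mp_with_ligand, dtype=float))
    boot_a = _boot(fit_a, y_a)
    boot_b = _boot(fit_b, y_b)
    n = min(len(boot_a), len(boot_b))
    ratios = boot_b[:n] / boot_a[:n]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    result.update(
        fit_with_ligand=fit_b,
        ic50_with_ligand=fit_b.ec50,
        ic50_ratio=float(ratio),
        ratio_ci=(float(lo), float(hi)),
        changed=not (lo <= 1.0 <= hi),
    )
    return result


# ---------------------------------------------------------------------------
# ELISA standard-curve intrapolation


@dataclass
class ElisaStandardCurve:
    fit: DoseResponseFit
    signal_min: float
    signal_max: float


def fit_elisa_standard(concentration, signal) -> ElisaStandardCurve:
    """4PL standard curve for sandwich-ELISA absorbances (rising with conc)."""
    fit = fit_4pl(concentration, signal, direction="activation")
    s = np.asarray(signal, dtype=float)
    return ElisaStandardCurve(fit, float(s.min()), float(s.max()))


def elisa_intrapolate(curve: ElisaStandardCurve, sample_signal) -> list[dict]:
    """Inverse-4PL concentration per sample, intrapolation only.

    Samples whose signal falls outside the standards' signal range are
    flagged ``out_of_range`` with concentration None, never extrapolated.
    """
    p = curve.fit.params
    out = []
    for s in np.atleast_1d(np.asarray(sample_signal, dtype=float)):
        if s < curve.signal_min or s > curve.signal_max:
            out.append({"signal": float(s), "concentration": None, "status": "out_of_range"})
            continue
        # invert y = bottom + (top-bottom)/(1+(ec50/x)^hill)
        frac = (p.top - p.bottom) / (s - p.bottom) - 1.0
        conc = p.ec50 / frac ** (1.0 / p.hill) if frac > 0 else np.inf
        out.append({"signal": float(s), "concentration": float(conc), "status": "ok"})
    return out


# ---------------------------------------------------------------------------
# qPCR ΔΔCt


def ddct_fold_change(ct_table, reference_gene: str, calibrator_sample: str):
    """2^−ΔΔCt relative expression per (gene, sample).

    ``ct_table`` is a DataFrame (gene, sample, ct).  ΔCt = Ct_gene −
    Ct_reference within each sample; ΔΔCt = ΔCt_sample − ΔCt_calibrator;
    fold change = 2^−ΔΔCt.  The calibrator sample (e.g. time-matched DMSO
    control) therefore has fold change 1 for every gene.
    """
    import pandas as pd

    t = pd.DataFrame(ct_table)
    if not np.all(np.isfinite(t["ct"])):
        raise ValueError("non-finite Ct values")
    wide = t.pivot(index="sample", columns="gene", values="ct")
    if reference_gene not in wide.columns or wide[reference_gene].isna().any():
        raise ValueError(f"reference gene {reference_gene!r} missing in some sample")
    if calibrator_sample not in wide.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")
    dct = wide.sub(wide[reference_gene], axis=0)
    ddct = dct.sub(dct.loc[calibrator_sample], axis=1)
    fold = 2.0 ** (-ddct)
    out = fold.drop(columns=reference_gene).reset_index().melt(
        id_vars="sample", var_name="gene", value_name="fold_change"
    )
    return out.sort_values(["gene", "sample"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Phagocytosis


def percent_phagocytosis(
    signal: float, background: float, reference_signal: float, reference_background: float
) -> float:
    """Net background-corrected fluorescence relative to the vehicle control,
    expressed as percent phagocytic activity."""
    ref_net = reference_signal - reference_background
    if ref_net <= 0:
        raise ValueError("nonpositive reference net signal")
    return float(100.0 * (signal - background) / ref_net)
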