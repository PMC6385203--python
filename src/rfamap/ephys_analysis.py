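"""Quantification of acid-evoked ion-channel current modulation.

Covers the analysis chain of a two-electrode voltage-clamp study of ASIC
currents modulated by an RFamide peptide:

* per-trace metrics — baseline, peak, sustained current (mean over the last
  two seconds of the acid application) and the I_sust/I_peak ratio;
* steady-state desensitization (SSD) curves fitted to the Hill form
  I = Imax * (1 - 1 / (1 + (10^-pHD50 / 10^-pH)^nH));
* concentration–response curves fitted to the Hill–Langmuir equation
  r(c) = r0 + (rmax - r0) * c^h / (EC50^h + c^h);
* mono-exponential association/dissociation kinetics with a
  pseudo-first-order k_on = k_obs / [L] (a two-state variant
  k_on = (k_obs - k_off) / [L] is available by flag);
* WT-vs-mutant effect classification producing the </=/> symbols of a
  modulation summary table (Welch tests, optional Holm correction across
  mutants).

All fits are Levenberg–Marquardt nonlinear least squares with three
deterministic data-driven starts (midpoint estimate and ±0.5 log-units) to
avoid local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StimulusProtocol",
    "CurrentTrace",
    "TraceMetrics",
    "SSDFit",
    "DoseResponseFit",
    "KineticFit",
    "ModulationReplicates",
    "ModulationComparison",
    "FitError",
    "ssd_hill",
    "hill_langmuir",
    "trace_metrics",
    "fit_ssd",
    "fit_dose_response",
    "fit_exponential_kinetics",
    "compare_modulation",
    "modulation_table",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed or did not converge."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StimulusProtocol:
    """Timing and chemistry of one acid application."""

    acid_start: float  # s
    acid_end: float    # s
    conditioning_pH: float = 7.4
    acid_pH: float = 5.0
    ligand_conc: float = 0.0  # mol/L; 0 = no peptide

    def __post_init__(self) -> None:
        if self.acid_end <= self.acid_start:
            raise ValueError("acid_end must be after acid_start")


@dataclass
class CurrentTrace:
    """Uniformly sampled current recording (inward currents negative, µA)."""

    t: np.ndarray
    i: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.i = np.asarray(self.i, float)
        if self.t.shape != self.i.shape or self.t.ndim != 1:
            raise ValueError("t and i must be equal-length 1-D arrays")
        if len(self.t) < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class TraceMetrics:
    i_peak: float
    i_sust: float
    ratio: float
    baseline: float
    usable: bool = True


@dataclass
class SSDFit:
    """Steady-state desensitization Hill fit: midpoint pHD50, slope nH."""

    pHD50: float
    nH: float
    Imax: float
    covariance: np.ndarray

    def __call__(self, pH):
        return ssd_hill(np.asarray(pH, float), self.pHD50, self.nH, self.Imax)


@dataclass
class DoseResponseFit:
    EC50: float  # mol/L
    hill: float
    r_max: float
    r_0: float
    covariance: np.ndarray

    def __call__(self, conc):
        return hill_langmuir(np.asarray(conc, float), self.EC50, self.hill,
                             self.r_max, self.r_0)


@dataclass
class KineticFit:
    rate: float  # s^-1 (k_off for decay, k_obs for rise)
    k_on: float | None
    amplitude: float
    offset: float


@dataclass
class ModulationReplicates:
    """Per-cell readouts of one genotype needed for the summary-table symbols.

    isust_fold: peptide-induced fold increase of I_sust/I_peak per cell;
    delta_pHD50: pHD50(peptide) - pHD50(control) per cell or session;
    nH_ratio: nH(peptide)/nH(control) per cell or session.
    """

    isust_fold: np.ndarray
    delta_pHD50: np.ndarray
    nH_ratio: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.isust_fold = np.asarray(self.isust_fold, float)
        self.delta_pHD50 = np.asarray(self.delta_pHD50, float)
        self.nH_ratio = np.asarray(self.nH_ratio, float)


@dataclass
class ModulationComparison:
    fold_change_ratio: float          # mutant fold increase / WT fold increase
    delta_pHD50: dict[str, float]     # per genotype means
    nH_ratio: dict[str, float]
    symbols: dict[str, str]           # {"isust","dpHD50","nH"} -> "<" | "=" | ">"
    p_values: dict[str, float]


# ---------------------------------------------------------------------------
# trace metrics
# ---------------------------------------------------------------------------


def trace_metrics(trace: CurrentTrace, baseline_window: float = 2.0,
                  sustained_window: float = 2.0,
                  noise_floor: float = 0.0) -> TraceMetrics:
    """Baseline, peak and sustained amplitude of one acid application.

    The baseline is the mean current just before the acid switch; peak is
    the largest baseline-subtracted absolute amplitude within the acid
    window; the sustained current is the mean amplitude over the last
    ``sustained_window`` seconds of the acid application.  Results are
    reported as positive magnitudes, so they are invariant to a constant
    offset and to the sign convention of the recording.
    """
    p = trace.protocol
    if p.acid_end - p.acid_start < sustained_window:
        raise ValueError(
            f"acid window ({p.acid_end - p.acid_start:.2f} s) shorter than the "
            f"{sustained_window:.1f} s sustained-current window")
    if p.acid_end > trace.t[-1] + 1e-9 or p.acid_start < trace.t[0] - 1e-9:
        raise ValueError("stimulus window exceeds trace extent")

    pre = (trace.t >= p.acid_start - baseline_window) & (trace.t < p.acid_start)
    if not pre.any():
        raise ValueError("no samples in the baseline window before acid_start")
    baseline = float(trace.i[pre].mean())

    acid = (trace.t >= p.acid_start) & (trace.t <= p.acid_end)
    dev = np.abs(trace.i[acid] - baseline)
    i_peak = float(dev.max())

    tail = (trace.t >= p.acid_end - sustained_window) & (trace.t <= p.acid_end)
    i_sust = float(np.abs(trace.i[tail] - baseline).mean())

    usable = i_peak > noise_floor
    ratio = i_sust / i_peak if i_peak != 0 else float("nan")
    return TraceMetrics(i_peak=i_peak, i_sust=i_sust, ratio=ratio,
                        baseline=baseline, usable=usable)


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------


def ssd_hill(pH, pHD50, nH, Imax):
    """Available current after conditioning at ``pH``.

    Equivalent to Imax * (1 - 1/(1 + (10^-pHD50 / 10^-pH)^nH)): full current
    at alkaline conditioning pH, none once conditioning desensitizes all
    channels.
    """
    return Imax * (1.0 - 1.0 / (1.0 + 10.0 ** (nH * (np.asarray(pH, float) - pHD50))))


def hill_langmuir(conc, ec50, hill, r_max, r_0):
    c = np.asarray(conc, float)
    ch = np.where(c > 0, c, 0.0) ** hill
    return r_0 + (r_max - r_0) * ch / (ec50 ** hill + ch)


def _best_fit(model, x, y, starts, bounds) -> tuple[np.ndarray, np.ndarray]:
    """curve_fit over several deterministic starts; lowest-RSS result wins."""
    best = None
    last_err: Exception | None = None
    lo, hi = (np.asarray(b, float) for b in bounds)
    for p0 in starts:
        p0 = np.minimum(np.maximum(np.asarray(p0, float), lo), hi)
        try:
            popt, pcov = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds,
                                            maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitError(f"fit did not converge from any start: {last_err}")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# SSD fit
# ---------------------------------------------------------------------------


def fit_ssd(cond_pH: Sequence[float], i_norm: Sequence[float]) -> SSDFit:
    """Fit the SSD Hill curve; the fitted curve passes Imax/2 at pHD50."""
    pH = np.asarray(cond_pH, float)
    y = np.asarray(i_norm, float)
    if len(np.unique(pH)) < 4:
        raise FitError("need >= 4 distinct conditioning pH values")
    if np.ptp(y) < 1e-12:
        raise FitError("degenerate SSD data: responses are all equal")

    imax0 = float(y.max())
    # midpoint start: pH where the response crosses half max
    order = np.argsort(pH)
    ph_s, y_s = pH[order], y[order]
    half = imax0 / 2.0
    above = np.nonzero(y_s >= half)[0]
    ph_half = float(ph_s[above[0]]) if above.size else float(np.median(pH))

    bounds = ([pH.min() - 2.0, 1e-3, 1e-12], [pH.max() + 2.0, 50.0, np.inf])
    starts = [(ph_half, 3.0, imax0), (ph_half - 0.5, 1.0, imax0),
              (ph_half + 0.5, 1.0, imax0)]
    popt, pcov = _best_fit(ssd_hill, pH, y, starts, bounds)
    return SSDFit(pHD50=float(popt[0]), nH=float(popt[1]), Imax=float(popt[2]),
                  covariance=pcov)


# ---------------------------------------------------------------------------
# concentration-response fit
# ---------------------------------------------------------------------------


def fit_dose_response(conc: Sequence[float], ratios: Sequence[float]) -> DoseResponseFit:
    """Hill–Langmuir fit of a concentration–response series (conc in mol/L)."""
    c = np.asarray(conc, float)
    y = np.asarray(ratios, float)
    if len(np.unique(c)) < 4:
        raise FitError("need >= 4 distinct concentrations")
    if np.allclose(y, 0):
        raise FitError("all responses are zero")
    pos = c[c > 0]
    if pos.size < 2:
        raise FitError("need at least two non-zero concentrations")

    def model(cc, log_ec50, hill, r_max, r_0):
        return hill_langmuir(cc, 10.0 ** log_ec50, hill, r_max, r_0)

    r0_0 = float(y[np.argmin(c)])
    rmax_0 = float(y[np.argmax(c)])
    half = (r0_0 + rmax_0) / 2.0
    order = np.argsort(c)
    idx = np.nonzero(y[order] >= half)[0]
    ec50_0 = float(c[order][idx[0]]) if idx.size and c[order][idx[0]] > 0 \
        else float(np.sqrt(pos.min() * pos.max()))
    lg = np.log10(ec50_0)

    lo = [np.log10(pos.min()) - 3, 0.05, -np.inf, -np.inf]
    hi = [np.log10(pos.max()) + 3, 10.0, np.inf, np.inf]
    starts = [(lg, 1.0, rmax_0, r0_0), (lg - 0.5, 1.0, rmax_0, r0_0),
              (lg + 0.5, 1.0, rmax_0, r0_0)]
    popt, pcov = _best_fit(model, c, y, starts, (lo, hi))
    return DoseResponseFit(EC50=float(10.0 ** popt[0]), hill=float(popt[1]),
                           r_max=float(popt[2]), r_0=float(popt[3]),
                           covariance=pcov)


# ---------------------------------------------------------------------------
# exponential kinetics
# ---------------------------------------------------------------------------


def fit_exponential_kinetics(t: Sequence[float], y: Sequence[float],
                             mode: Literal["decay", "rise"] = "decay",
                             ligand_conc: float | None = None,
                             kon_model: Literal["pseudo_first_order", "two_state"]
                             = "pseudo_first_order",
                             k_off: float | None = None) -> KineticFit:
    """Mono-exponential fit of ligand-effect onset or washout.

    decay: y = A exp(-rate t) + offset (rate = k_off);
    rise:  y = A (1 - exp(-rate t)) + offset (rate = k_obs).
    With ``ligand_conc`` given, the association rate constant follows the
    pseudo-first-order form k_on = k_obs/[L], or the two-state form
    k_on = (k_obs - k_off)/[L] when requested.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 4:
        raise FitError("need >= 4 time points")
    if np.ptp(y) < 1e-14:
        raise FitError("constant signal: rate is unidentifiable")

    span = float(t.max() - t.min()) or 1.0
    k0 = 3.0 / span

    if mode == "decay":
        def model(tt, a, k, off):
            return a * np.exp(-k * tt) + off
        a0, off0 = float(y[0] - y[-1]), float(y[-1])
    elif mode == "rise":
        def model(tt, a, k, off):
            return a * (1.0 - np.exp(-k * tt)) + off
        a0, off0 = float(y[-1] - y[0]), float(y[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    scale = max(abs(a0), np.ptp(y), 1e-12)
    bounds = ([-10 * scale, 1e-9, -np.inf], [10 * scale, 1e6, np.inf])
    starts = [(a0, k0, off0), (a0, k0 * 10 ** 0.5, off0), (a0, k0 * 10 ** -0.5, off0)]
    popt, _ = _best_fit(model, t, y, starts, bounds)
    a, rate, off = (float(v) for v in popt)
    if rate <= 0:
        raise FitError(f"fitted rate is non-positive ({rate})")

    k_on = None
    if ligand_conc is not None:
        if ligand_conc <= 0:
            raise ValueError("ligand_conc must be > 0 to derive k_on")
        if kon_model == "pseudo_first_order":
            k_on = rate / ligand_conc
        elif kon_model == "two_state":
            if k_off is None:
                raise ValueError("two_state k_on needs k_off")
            k_on = (rate - k_off) / ligand_conc
        else:
            raise ValueError(f"unknown kon_model {kon_model!r}")
    return KineticFit(rate=rate, k_on=k_on, amplitude=a, offset=off)


# ---------------------------------------------------------------------------
# WT vs mutant classification
# ---------------------------------------------------------------------------

_PARAMS = ("isust", "dpHD50", "nH")


def _symbol(wt: np.ndarray, mut: np.ndarray, alpha: float,
            p_override: float | None = None) -> tuple[str, float]:
    t, p = stats.ttest_ind(mut, wt, equal_var=False)
    p_eff = p_override if p_override is not None else p
    if np.isnan(p_eff) or p_eff >= alpha:
        return "=", float(p)
    return ("<" if mut.mean() < wt.mean() else ">"), float(p)


def compare_modulation(wt: ModulationReplicates, mut: ModulationReplicates,
                       alpha: float = 0.05,
                       adjusted_p: dict[str, float] | None = None) -> ModulationComparison:
    """Classify a mutant against WT into </=/> per modulation parameter.

    Symbols indicate whether the peptide changed a parameter differently in
    the mutant: the peptide-induced I_sust/I_peak fold increase, the
    peptide-induced pHD50 shift, and the nH(peptide)/nH(control) ratio.
    Welch t-tests at level ``alpha``; ``adjusted_p`` lets a multi-mutant
    caller substitute Holm-corrected p-values.
    """
    for grp in (wt, mut):
        for arr in (grp.isust_fold, grp.delta_pHD50, grp.nH_ratio):
            if arr.size < 3:
                raise ValueError(
                    f"genotype {grp.name or '?'}: need >= 3 replicates per parameter")
    pairs = {
        "isust": (wt.isust_fold, mut.isust_fold),
        "dpHD50": (wt.delta_pHD50, mut.delta_pHD50),
        "nH": (wt.nH_ratio, mut.nH_ratio),
    }
    symbols, pvals = {}, {}
    for name, (w, m) in pairs.items():
        sym, p = _symbol(w, m, alpha,
                         (adjusted_p or {}).get(name))
        symbols[name] = sym
        pvals[name] = p
    return ModulationComparison(
        fold_change_ratio=float(mut.isust_fold.mean() / wt.isust_fold.mean()),
        delta_pHD50={"wt": float(wt.delta_pHD50.mean()),
                     "mutant": float(mut.delta_pHD50.mean())},
        nH_ratio={"wt": float(wt.nH_ratio.mean()),
                  "mutant": float(mut.nH_ratio.mean())},
        symbols=symbols,
        p_values=pvals,
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def modulation_table(wt: ModulationReplicates,
                     mutants: dict[str, ModulationReplicates],
                     alpha: float = 0.05) -> dict[str, ModulationComparison]:
    """Compare several mutants against WT with Holm correction per parameter."""
    names = sorted(mutants)
    raw: dict[str, dict[str, float]] = {p: {} for p in _PARAMS}
    for nm in names:
        cmpn = compare_modulation(wt, mutants[nm], alpha=alpha)
        for p in _PARAMS:
            raw[p][nm] = cmpn.p_values[p]
    adjusted: dict[str, dict[str, float]] = {nm: {} for nm in names}
    for p in _PARAMS:
        adj = _holm(np.array([raw[p][nm] for nm in names]))
        for nm, a in zip(names, adj):
            adjusted[nm][p] = float(a)
    return {nm: compare_modulation(wt, mutants[nm], alpha=alpha,
                                   adjusted_p=adjusted[nm])
            for nm in names}
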