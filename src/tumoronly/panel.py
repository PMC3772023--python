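"""Panel-based germline exclusion and its discriminative power.

The filter removes from a tumor candidate list every variant seen in at
least one external germline exome ("crude" somatic set); subtraction of
the matched normal yields the "refined" set.  The discriminative power
of a panel of size k is the detection sensitivity: the fraction of a
patient's true germline variants carried by at least one of the k panel
exomes, averaged over patients and over k-subsets of the panel
(exhaustively when the number of combinations is small, otherwise over
a capped random subsample, ~10,000 by default).

Saturation of sensitivity in k is extrapolated two ways:

* an exponential model S(k) = s_max (1 - e^(-k/tau)) fitted to the
  curve (:func:`fit_saturation_curve`), and
* a binomial-mixture deconvolution of the panel carrier-count spectrum
  (:func:`fit_carrier_spectrum`), which is much better conditioned for
  extrapolation far beyond the observed panel sizes because it
  estimates the carrier-frequency spectrum directly.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, nnls
from scipy.special import gammaln
from scipy.stats import binom

from .variants import CallSet, PanelCollection, VariantKey

__all__ = [
    "CurvePoint",
    "SensitivityCurve",
    "SaturationFit",
    "FitError",
    "apply_panel_filter",
    "refine_with_matched_normal",
    "estimate_detection_sensitivity",
    "mean_sensitivity_exact",
    "sensitivity_curve",
    "sensitivity_by_frequency",
    "fit_saturation_curve",
    "fit_carrier_spectrum",
    "required_panel_size",
    "compare_panels",
]


class FitError(RuntimeError):
    """Saturation fit failed (degenerate or non-convergent data)."""


# ---------------------------------------------------------------------------
# filtering


def apply_panel_filter(tumor_calls: CallSet, panel: PanelCollection) -> CallSet:
    """Remove tumor variants present in any panel individual (crude somatic set)."""
    union = panel.site_union()
    keep = tumor_calls.variants - union
    return CallSet(
        sample_id=tumor_calls.sample_id,
        variants=keep,
        attrs={k: dict(tumor_calls.attrs[k]) for k in keep if k in tumor_calls.attrs},
    )


def refine_with_matched_normal(tumor_calls: CallSet, normal_calls: CallSet) -> CallSet:
    """Subtract the matched normal (refined somatic set); patients must match."""
    if tumor_calls.sample_id != normal_calls.sample_id:
        raise ValueError(
            f"mismatched patients: tumor {tumor_calls.sample_id!r} vs "
            f"normal {normal_calls.sample_id!r}"
        )
    keep = tumor_calls.variants - normal_calls.variants
    return CallSet(
        sample_id=tumor_calls.sample_id,
        variants=keep,
        attrs={k: dict(tumor_calls.attrs[k]) for k in keep if k in tumor_calls.attrs},
    )


# ---------------------------------------------------------------------------
# sensitivity machinery


@dataclasses.dataclass(frozen=True)
class CurvePoint:
    k: int
    mean_sensitivity: float
    sd: float
    n_combos: int  # 0 marks the analytic average over all C(n, k) subsets


@dataclasses.dataclass
class SensitivityCurve:
    """Mean germline-detection sensitivity vs panel size."""

    points: list[CurvePoint]
    population_label: str = ""

    def __post_init__(self):
        ks = [p.k for p in self.points]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("panel sizes k must be strictly increasing")
        for p in self.points:
            if not (0.0 <= p.mean_sensitivity <= 1.0):
                raise ValueError(f"sensitivity {p.mean_sensitivity} outside [0, 1]")

    @property
    def k(self) -> np.ndarray:
        return np.array([p.k for p in self.points])

    @property
    def sensitivity(self) -> np.ndarray:
        return np.array([p.mean_sensitivity for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.k, p.mean_sensitivity, p.sd, p.n_combos) for p in self.points],
            columns=["k", "mean_sensitivity", "sd", "n_combos"],
        )


def _normalize_truth(
    germline_truth: Mapping[str, Iterable[VariantKey]] | Sequence[Iterable[VariantKey]],
) -> list[frozenset[VariantKey]]:
    if isinstance(germline_truth, Mapping):
        sets = [frozenset(v) for _, v in sorted(germline_truth.items())]
    else:
        sets = [frozenset(v) for v in germline_truth]
    sets = [s for s in sets if s]
    if not sets:
        raise ValueError("undefined sensitivity: no germline truth variants")
    return sets


class _BitIndex:
    """Packed-bit representation of truth and panel variant sets."""

    def __init__(self, truth_sets: list[frozenset[VariantKey]], panel: PanelCollection):
        universe = sorted(
            frozenset().union(*truth_sets), key=lambda v: (v.chrom, v.pos, v.ref, v.alt)
        )
        self.n_sites = len(universe)
        index = {v: i for i, v in enumerate(universe)}
        self.universe = universe
        t = np.zeros((len(truth_sets), self.n_sites), dtype=bool)
        for i, s in enumerate(truth_sets):
            t[i, [index[v] for v in s]] = True
        self.truth_bits = np.packbits(t, axis=1)
        self.truth_sizes = t.sum(axis=1)
        p = np.zeros((len(panel), self.n_sites), dtype=bool)
        for i, m in enumerate(panel.members):
            hit = [index[v] for v in m.variants if v in index]
            p[i, hit] = True
        self.panel_bits = np.packbits(p, axis=1)
        self.carrier_counts = p.sum(axis=0)

    def combo_sensitivity(self, combo: Sequence[int]) -> float:
        union = np.bitwise_or.reduce(self.panel_bits[list(combo)], axis=0)
        hits = np.bitwise_count(union[None, :] & self.truth_bits).sum(axis=1)
        return float(np.mean(hits / self.truth_sizes))


def _sample_combos(
    rng: np.random.Generator, n: int, k: int, max_combos: int
) -> list[tuple[int, ...]]:
    total = math.comb(n, k)
    if total <= max_combos:
        return list(itertools.combinations(range(n), k))
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    attempts = 0
    while len(out) < max_combos:
        c = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        attempts += 1
        if c in seen:
            if attempts > 50 * max_combos:
                break
            continue
        seen.add(c)
        out.append(c)
    return out


def estimate_detection_sensitivity(
    germline_truth: Mapping[str, Iterable[VariantKey]] | Sequence[Iterable[VariantKey]],
    panel: PanelCollection,
    k: int,
    max_combos: int = 10_000,
    seed: int | None = None,
) -> CurvePoint:
    """Subsampling estimate of panel detection sensitivity at size k.

    For each k-subset of the panel, the sensitivity is the fraction of a
    patient's germline variants present in the subset union, averaged
    over patients; the estimate is the mean (and sd) over all subsets
    when C(n, k) <= ``max_combos``, otherwise over ``max_combos``
    distinct uniformly drawn subsets.  Patients with empty truth sets
    are excluded; an entirely empty truth is an error.
    """
    truth = _normalize_truth(germline_truth)
    n = len(panel)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    bits = _BitIndex(truth, panel)
    rng = np.random.default_rng(seed)
    combos = _sample_combos(rng, n, k, max_combos)
    vals = np.array([bits.combo_sensitivity(c) for c in combos])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return CurvePoint(k=k, mean_sensitivity=float(vals.mean()), sd=sd, n_combos=len(vals))


def _exact_site_detection(carrier_counts: np.ndarray, n: int, k: int) -> np.ndarray:
    """P(site in union of a uniform k-subset) = 1 - C(n-c, k)/C(n, k)."""
    c = carrier_counts
    rem = n - c
    miss = np.zeros(len(c))
    ok = rem >= k
    if np.any(ok):
        miss[ok] = np.exp(
            gammaln(rem[ok] + 1)
            - gammaln(rem[ok] - k + 1)
            - (gammaln(n + 1) - gammaln(n - k + 1))
        )
    return 1.0 - miss


def mean_sensitivity_exact(
    germline_truth: Mapping[str, Iterable[VariantKey]] | Sequence[Iterable[VariantKey]],
    panel: PanelCollection,
    k: int,
) -> float:
    """Exact mean sensitivity over all C(n, k) panel subsets.

    Uses the per-site hypergeometric identity: a site carried by c of
    the n panel exomes is missed by a uniform k-subset with probability
    C(n-c, k)/C(n, k).  Equals the limit of the subsampling estimator.
    """
    truth = _normalize_truth(germline_truth)
    n = len(panel)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    bits = _BitIndex(truth, panel)
    det = _exact_site_detection(bits.carrier_counts, n, k)
    per_patient = []
    unpacked = np.unpackbits(bits.truth_bits, axis=1, count=bits.n_sites).astype(bool)
    for i in range(unpacked.shape[0]):
        per_patient.append(det[unpacked[i]].mean())
    return float(np.mean(per_patient))


def sensitivity_curve(
    germline_truth,
    panel: PanelCollection,
    k_grid: Sequence[int],
    max_combos: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> SensitivityCurve:
    """Sensitivity at each panel size in ``k_grid`` (capped at the panel size)."""
    ks = sorted({int(k) for k in k_grid if 1 <= k <= len(panel)})
    if not ks:
        raise ValueError("k_grid contains no feasible panel sizes")
    pts = []
    rng = np.random.default_rng(seed)
    for k in ks:
        if exact:
            s = mean_sensitivity_exact(germline_truth, panel, k)
            pts.append(CurvePoint(k=k, mean_sensitivity=s, sd=0.0, n_combos=0))
        else:
            sub = int(rng.integers(0, 2**31 - 1))
            pts.append(
                estimate_detection_sensitivity(germline_truth, panel, k, max_combos, sub)
            )
    return SensitivityCurve(points=pts, population_label=panel.label)


def sensitivity_by_frequency(
    germline_truth,
    cohort_frequencies: Mapping[VariantKey, float],
    panel: PanelCollection,
    k: int,
    bins: Sequence[float],
) -> pd.DataFrame:
    """Detection sensitivity stratified by cohort occurrence frequency.

    ``bins`` are increasing upper edges partitioning (0, 1]; bin i is
    (edge[i-1], edge[i]].  Within each bin, each patient's sensitivity
    is computed over their variants in the bin (exact, averaged over all
    k-subsets) and averaged over patients with at least one such
    variant; an empty bin is reported as NaN, not 0.
    """
    edges = list(bins)
    if not edges or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bins must be strictly increasing upper edges")
    if not (0 < edges[0] and abs(edges[-1] - 1.0) < 1e-12):
        raise ValueError("bins must partition (0, 1]: last edge must be 1.0")
    truth = _normalize_truth(germline_truth)
    for s in truth:
        for v in s:
            if v not in cohort_frequencies:
                raise ValueError(f"variant {v} missing from the frequency map")
    n = len(panel)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    bits = _BitIndex(truth, panel)
    det = _exact_site_detection(bits.carrier_counts, n, k)
    freqs = np.array([cohort_frequencies[v] for v in bits.universe])
    which = np.searchsorted(np.array(edges), freqs, side="left")
    unpacked = np.unpackbits(bits.truth_bits, axis=1, count=bits.n_sites).astype(bool)
    rows = []
    lo = 0.0
    for b, hi in enumerate(edges):
        sel = which == b
        per_patient = []
        n_inst = 0
        for i in range(unpacked.shape[0]):
            mask = unpacked[i] & sel
            cnt = int(mask.sum())
            if cnt:
                per_patient.append(det[mask].mean())
                n_inst += cnt
        sens = float(np.mean(per_patient)) if per_patient else float("nan")
        rows.append((lo, hi, sens, n_inst))
        lo = hi
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "sensitivity", "n_instances"])


# ---------------------------------------------------------------------------
# saturation models


@dataclasses.dataclass
class SaturationFit:
    """Fitted saturation model of sensitivity vs panel size.

    ``model`` is ``"exponential"`` (S(k) = s_max (1 - e^(-k/tau))) or
    ``"mixture"`` (S(k) = sum_j w_j (1 - (1 - q_j)^k)).
    """

    model: str
    s_max: float
    tau: float | None = None
    weights: np.ndarray | None = None
    qs: np.ndarray | None = None
    residual_rms: float = float("nan")

    def predict(self, k):
        k = np.asarray(k, dtype=float)
        if self.model == "exponential":
            out = self.s_max * -np.expm1(-k / self.tau)
        else:
            out = (self.weights * (1.0 - (1.0 - self.qs) ** k[..., None])).sum(axis=-1)
        return out if out.shape else float(out)


def fit_saturation_curve(
    curve: SensitivityCurve,
    model: str = "exponential",
    q_grid: Sequence[float] | None = None,
) -> SaturationFit:
    """Least-squares saturation fit of a sensitivity curve.

    The default exponential form constrains s_max to [0, 1].  The
    mixture form fits non-negative weights over the carrier-probability
    grid ``q_grid`` (required); use it when the population's frequency
    classes are known.
    """
    k = curve.k.astype(float)
    s = curve.sensitivity
    if len(k) < 3:
        raise ValueError("need at least 3 curve points with distinct k")
    if float(np.ptp(s)) < 1e-12:
        raise FitError("degenerate curve: all sensitivities equal")
    if model == "exponential":
        def f(kk, smax, tau):
            return smax * -np.expm1(-kk / tau)

        p0 = (min(1.0, max(s.max(), 1e-3)), max(k.mean(), 1.0))
        try:
            popt, _ = curve_fit(
                f, k, s, p0=p0, bounds=([0.0, 1e-9], [1.0, 1e9]), maxfev=20_000
            )
        except RuntimeError as exc:
            raise FitError(f"saturation fit did not converge: {exc}") from exc
        resid = s - f(k, *popt)
        return SaturationFit(
            model="exponential",
            s_max=float(popt[0]),
            tau=float(popt[1]),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )
    if model == "mixture":
        if q_grid is None:
            raise ValueError("mixture fit requires q_grid (carrier probabilities)")
        qs = np.asarray(q_grid, dtype=float)
        A = 1.0 - (1.0 - qs[None, :]) ** k[:, None]
        w, _ = nnls(A, s)
        resid = s - A @ w
        return SaturationFit(
            model="mixture",
            s_max=float(w.sum()),
            weights=w,
            qs=qs,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )
    raise ValueError(f"unknown saturation model {model!r}")


def default_spectrum_grid(n_points: int = 40) -> np.ndarray:
    """Log-spaced carrier-probability grid for spectrum deconvolution."""
    return np.logspace(-4.3, math.log10(0.6), n_points)


def fit_carrier_spectrum(
    germline_truth,
    panel: PanelCollection,
    q_grid: Sequence[float] | None = None,
) -> SaturationFit:
    """Deconvolve the carrier-frequency spectrum from panel carrier counts.

    Each truth variant is carried by c of the n panel exomes; c follows
    Binomial(n, q) for a variant of carrier probability q.  Non-negative
    least squares against binomial profiles over ``q_grid`` yields
    spectrum weights (instance-weighted by how many patients carry the
    variant), from which sensitivity at any panel size follows as
    S(k) = sum_j w_j (1 - (1 - q_j)^k).  This extrapolates far beyond
    the observed panel size much more stably than a fit to the k-curve.
    """
    truth = _normalize_truth(germline_truth)
    bits = _BitIndex(truth, panel)
    n = len(panel)
    qs = default_spectrum_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    unpacked = np.unpackbits(bits.truth_bits, axis=1, count=bits.n_sites)
    inst_weight = unpacked.sum(axis=0).astype(float)  # patients carrying each site
    hist = np.bincount(bits.carrier_counts, weights=inst_weight, minlength=n + 1)
    hist = hist / hist.sum()
    B = binom.pmf(np.arange(n + 1)[:, None], n, qs[None, :])
    w, _ = nnls(B, hist)
    if w.sum() <= 0:
        raise FitError("spectrum deconvolution returned an empty mixture")
    w = w / w.sum()
    resid = hist - B @ w
    return SaturationFit(
        model="mixture",
        s_max=float(w.sum()),
        weights=w,
        qs=qs,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def required_panel_size(fit: SaturationFit, target_sensitivity: float) -> int:
    """Smallest panel size k with predicted S(k) >= target.

    Raises ``ValueError`` if the target is at or above the fitted
    asymptote ("target exceeds asymptote").
    """
    t = float(target_sensitivity)
    if not (0.0 < t < 1.0):
        raise ValueError("target sensitivity must lie in (0, 1)")
    if t >= fit.s_max * (1.0 - 1e-12):
        raise ValueError(
            f"target {t} exceeds asymptote: fitted maximum sensitivity is {fit.s_max:.4f}"
        )
    if fit.model == "exponential":
        k = math.ceil(-fit.tau * math.log1p(-t / fit.s_max))
        k = max(k, 1)
        while float(fit.predict(k)) < t:  # guard against float rounding of ceil
            k += 1
        return k
    lo, hi = 1, 2
    while float(fit.predict(hi)) < t:
        hi *= 2
        if hi > 10**8:
            raise ValueError("target not reached below 1e8 panel exomes")
    while lo < hi:
        mid = (lo + hi) // 2
        if float(fit.predict(mid)) >= t:
            hi = mid
        else:
            lo = mid + 1
    return lo


def compare_panels(
    germline_truth,
    panels: Sequence[PanelCollection],
    k_grid: Sequence[int],
    max_combos: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> list[SensitivityCurve]:
    """One sensitivity curve per panel on a common k grid (k capped per panel)."""
    if not panels:
        raise ValueError("at least one panel is required")
    for p in panels:
        if len(p) == 0:
            raise ValueError(f"panel {p.label!r} is empty")
    rng = np.random.default_rng(seed)
    out = []
    for p in panels:
        sub = int(rng.integers(0, 2**31 - 1))
        out.append(sensitivity_curve(germline_truth, p, k_grid, max_combos, sub, exact=exact))
    return out
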