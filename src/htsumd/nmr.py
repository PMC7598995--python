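"""The NMR screening calculus used to validate the computational screen.

Implements the arithmetic of a mixture-based fragment screen against a
¹⁵N-labelled protein:

* **CSP** — amide chemical-shift perturbation combining the ¹H and ¹⁵N shift
  changes with the nitrogen dimension down-weighted five-fold,

      ddNH = sqrt( (ddH^2 + (ddN/5)^2) / 2 )   [ppm].

* **Mixture classes** — the mean CSP over the monitored peak panel sorts a
  mixture into first class (> 0.35 ppm), second class (0.25-0.35 ppm], or
  discard (<= 0.25 ppm).

* **STD amplification factor** —

      fSTD = (I_STD^prot - I_STD^0) / I_0 * [L]_tot/[P]_tot * 100,

  binder iff fSTD >= 50.

* **WaterLOGSY** — binder when at least one ligand peak flips from positive
  (free) to negative (with protein); a negative control peak makes the call
  ambiguous.

* **Mixture design** — a seeded greedy + pairwise-swap assignment minimising
  1D ¹H peak overlap (pairs closer than 0.03 ppm) inside each mixture.

* **Single-site Kd fit** — grid search over Kd with the exact quadratic
  bound-fraction (no ligand-excess approximation),

      f_b = ([P]+[L]+Kd - sqrt(([P]+[L]+Kd)^2 - 4[P][L])) / (2[P]),

  with the saturated shift profiled in closed form per Kd grid point and a
  nested linear refinement; reported as mean +/- sd over >= 3 peaks.

* **Additivity deconvolution** — singles should explain the mixture CSP to
  first order; an unexplained residual flags probable false negatives of the
  ligand-observed experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, UnidentifiableError, ValidationError

NITROGEN_WEIGHT = 5.0


# ---------------------------------------------------------------------------
# peaks and CSP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    residue: str
    d1h: float     # ppm
    d15n: float    # ppm

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d1h) and np.isfinite(self.d15n)):
            raise ValidationError("non-finite chemical shift")


def csp(apo: Peak, mix: Peak) -> float:
    """Amide CSP (ppm) between the apo spectrum and the mixture spectrum."""
    if apo.residue != mix.residue:
        raise ValidationError(
            f"peak pairing mismatch: {apo.residue} vs {mix.residue}")
    dh = mix.d1h - apo.d1h
    dn = (mix.d15n - apo.d15n) / NITROGEN_WEIGHT
    return float(np.sqrt((dh * dh + dn * dn) / 2.0))


@dataclass
class CspResult:
    per_peak: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_peak.values()):
            raise ValidationError("CSP values are non-negative by definition")

    @property
    def mean(self) -> float:
        if not self.per_peak:
            raise ValidationError("empty peak panel")
        return float(np.mean(list(self.per_peak.values())))


def csp_panel(apo_peaks: dict[str, Peak],
              mix_peaks: dict[str, Peak],
              panel: list[str] | None = None) -> CspResult:
    """CSPs over a monitored peak panel (default: all shared residues)."""
    panel = panel or sorted(set(apo_peaks) & set(mix_peaks))
    return CspResult({r: csp(apo_peaks[r], mix_peaks[r]) for r in panel})


MIXTURE_FIRST = "first"
MIXTURE_SECOND = "second"
MIXTURE_DISCARD = "discard"


@dataclass(frozen=True)
class MixtureClassThresholds:
    first: float = 0.35     # ppm; mean CSP above this -> first class
    discard: float = 0.25   # ppm; mean CSP at or below this -> discard

    def __post_init__(self) -> None:
        if not self.first > self.discard > 0:
            raise ValueError("require first > discard > 0")


def classify_mixture(result: CspResult,
                     thresholds: MixtureClassThresholds | None = None) -> str:
    """Class from the mean CSP; the boundary 0.25 itself is discarded and
    0.35 itself is second class (strict '>' at both cut-offs)."""
    thresholds = thresholds or MixtureClassThresholds()
    mean = result.mean
    if mean > thresholds.first:
        return MIXTURE_FIRST
    if mean > thresholds.discard:
        return MIXTURE_SECOND
    return MIXTURE_DISCARD


# ---------------------------------------------------------------------------
# mixture design
# ---------------------------------------------------------------------------

@dataclass
class MixturePlan:
    mixtures: list[list[str]]
    overlap_cost: int
    seed: int


def _plan_cost(mixtures: list[list[str]], peaks: dict[str, np.ndarray],
               window: float) -> int:
    cost = 0
    for mix in mixtures:
        for i in range(len(mix)):
            for j in range(i + 1, len(mix)):
                a, b = peaks[mix[i]], peaks[mix[j]]
                cost += int(np.sum(
                    np.abs(a[:, None] - b[None, :]) < window))
    return cost


def design_mixtures(fragment_peaklists: dict[str, "np.ndarray | list"],
                    mixture_size: int = 5, window: float = 0.03,
                    seed: int = 0, max_sweeps: int = 20) -> MixturePlan:
    """Partition fragments into mixtures of ``mixture_size`` minimising 1D
    peak overlap; any remainder forms one smaller final mixture.

    Greedy seeded assignment (each fragment goes to the open mixture where it
    adds the least overlap) followed by pairwise-swap hill climbing; the
    overlap cost is non-increasing across sweeps.
    """
    if mixture_size < 2:
        raise ValidationError("mixture size must be at least 2")
    peaks = {f: np.asarray(p, dtype=float)
             for f, p in fragment_peaklists.items()}
    for f, p in peaks.items():
        if p.size == 0:
            raise ValidationError(f"fragment {f} has no peaks")
    names = sorted(peaks)
    n_mix = int(np.ceil(len(names) / mixture_size))
    rng = np.random.default_rng(seed)
    order = [names[i] for i in rng.permutation(len(names))]

    sizes = [mixture_size] * n_mix
    if len(names) % mixture_size:
        sizes[-1] = len(names) % mixture_size
    mixtures: list[list[str]] = [[] for _ in range(n_mix)]

    def pair_overlap(f1: str, f2: str) -> int:
        a, b = peaks[f1], peaks[f2]
        return int(np.sum(np.abs(a[:, None] - b[None, :]) < window))

    def mix_cost(mix: list[str]) -> int:
        return sum(pair_overlap(mix[i], mix[j])
                   for i in range(len(mix)) for j in range(i + 1, len(mix)))

    def added_cost(mix: list[str], frag: str) -> int:
        return sum(pair_overlap(frag, m) for m in mix)

    for frag in order:
        best, best_cost = None, None
        for mi, mix in enumerate(mixtures):
            if len(mix) >= sizes[mi]:
                continue
            c = added_cost(mix, frag)
            if best_cost is None or c < best_cost:
                best, best_cost = mi, c
        mixtures[best].append(frag)

    costs = [mix_cost(m) for m in mixtures]
    for _ in range(max_sweeps):
        improved = False
        for mi in range(n_mix):
            for mj in range(mi + 1, n_mix):
                for a in range(len(mixtures[mi])):
                    for b in range(len(mixtures[mj])):
                        mixtures[mi][a], mixtures[mj][b] = \
                            mixtures[mj][b], mixtures[mi][a]
                        ci, cj = mix_cost(mixtures[mi]), mix_cost(mixtures[mj])
                        if ci + cj < costs[mi] + costs[mj]:
                            costs[mi], costs[mj] = ci, cj
                            improved = True
                        else:
                            mixtures[mi][a], mixtures[mj][b] = \
                                mixtures[mj][b], mixtures[mi][a]
        if not improved:
            break
    cost = sum(costs)
    return MixturePlan(mixtures=[sorted(m) for m in mixtures],
                       overlap_cost=cost, seed=seed)


# ---------------------------------------------------------------------------
# ligand-observed experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StdMeasurement:
    i_std_prot: float    # STD peak integral with protein
    i_std_0: float       # STD peak integral without protein (control)
    i_0: float           # off-resonance reference integral
    l_tot: float         # total ligand concentration
    p_tot: float         # total protein concentration (same units)
    binder_cutoff: float = 50.0

    def __post_init__(self) -> None:
        if self.i_0 <= 0:
            raise ValidationError("off-resonance reference integral must be > 0")
        if self.l_tot <= 0 or self.p_tot <= 0:
            raise ValidationError("concentrations must be positive")


def fstd(m: StdMeasurement) -> tuple[float, bool]:
    """STD amplification factor and the binder flag (>= cutoff)."""
    value = (m.i_std_prot - m.i_std_0) / m.i_0 * (m.l_tot / m.p_tot) * 100.0
    return value, value >= m.binder_cutoff


WLOGSY_BINDER = "binder"
WLOGSY_NONBINDER = "non-binder"
WLOGSY_AMBIGUOUS = "ambiguous"


def waterlogsy_call(signs_without_protein: dict[str, int],
                    signs_with_protein: dict[str, int]) -> str:
    """Sign logic: a positive->negative flip upon adding protein indicates
    binding; a negative control peak voids the experiment."""
    if set(signs_without_protein) != set(signs_with_protein):
        raise ValidationError("peak sets must match between the two spectra")
    if any(s < 0 for s in signs_without_protein.values()):
        return WLOGSY_AMBIGUOUS
    flipped = any(signs_without_protein[p] > 0 and signs_with_protein[p] < 0
                  for p in signs_without_protein)
    return WLOGSY_BINDER if flipped else WLOGSY_NONBINDER


EVIDENCE_BINDER = "potential binder"
EVIDENCE_CONTROVERSIAL = "controversial"
EVIDENCE_NEGATIVE = "negative"


def combine_ligand_evidence(std_is_binder: bool, wlogsy_flag: str) -> str:
    """Only fragments positive in both ligand-observed experiments are
    potential binders; disagreement (or an ambiguous WaterLOGSY) is
    controversial and triggers individual re-testing."""
    wl_binder = wlogsy_flag == WLOGSY_BINDER
    if std_is_binder and wl_binder:
        return EVIDENCE_BINDER
    if not std_is_binder and wlogsy_flag == WLOGSY_NONBINDER:
        return EVIDENCE_NEGATIVE
    return EVIDENCE_CONTROVERSIAL


# ---------------------------------------------------------------------------
# single-site Kd fitting
# ---------------------------------------------------------------------------

@dataclass
class Titration:
    """Ligand-concentration series of observed shifts for several peaks."""

    ligand_conc: np.ndarray               # uM, strictly increasing from 0
    shifts: dict[str, np.ndarray]         # ppm, observed shift per peak
    protein_conc: float                   # uM

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.shifts = {k: np.asarray(v, dtype=float)
                       for k, v in self.shifts.items()}
        c = self.ligand_conc
        if c[0] != 0 or np.any(np.diff(c) <= 0):
            raise ValidationError(
                "ligand concentrations must increase strictly from 0")
        if len(c) < 4:
            raise ValidationError("need at least 4 titration points")
        for k, v in self.shifts.items():
            if len(v) != len(c):
                raise ValidationError(f"peak {k}: wrong number of shifts")
        if self.protein_conc <= 0:
            raise ValidationError("protein concentration must be positive")


@dataclass
class PeakFit:
    kd: float          # uM
    delta_sat: float   # ppm
    sse: float
    at_grid_edge: bool


@dataclass
class KdFit:
    per_peak: dict[str, PeakFit]
    kd_mean: float
    kd_sd: float


def bound_fraction(l_tot: np.ndarray, p_tot: float, kd: float) -> np.ndarray:
    """Exact single-site bound fraction of the protein."""
    l_tot = np.asarray(l_tot, dtype=float)
    s = p_tot + l_tot + kd
    return (s - np.sqrt(s * s - 4.0 * p_tot * l_tot)) / (2.0 * p_tot)


def default_kd_grid(lo: float = 1.0, hi: float = 1e5,
                    n: int = 200) -> np.ndarray:
    """Log-spaced Kd grid, 1 uM to 100 mM by default."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _fit_peak(conc, shifts, p_tot, grid, min_signal) -> PeakFit:
    delta_apo = shifts[0]
    y = shifts - delta_apo
    if np.max(np.abs(y)) < min_signal:
        raise UnidentifiableError("flat titration: no binding signal")

    def profile(kd_values):
        best = (np.inf, np.nan, np.nan)
        for kd in kd_values:
            fb = bound_fraction(conc, p_tot, kd)
            denom = float(fb @ fb)
            amp = float(fb @ y) / denom if denom > 0 else 0.0
            sse = float(np.sum((y - amp * fb) ** 2))
            if sse < best[0]:
                best = (sse, kd, amp)
        return best

    sse, kd, amp = profile(grid)
    idx = int(np.searchsorted(grid, kd))
    edge = idx <= 0 or idx >= len(grid) - 1
    if not edge:
        refined = np.linspace(grid[idx - 1], grid[idx + 1], 49)
        sse, kd, amp = profile(refined)
    else:
        warnings.warn("Kd estimate at the grid edge", stacklevel=2)
    return PeakFit(kd=float(kd), delta_sat=float(delta_apo + amp),
                   sse=sse, at_grid_edge=edge)


def fit_kd(titration: Titration, grid: np.ndarray | None = None,
           min_peaks: int = 3, min_signal: float = 1e-4) -> KdFit:
    """Per-peak grid-search single-site fits, summarised as mean +/- sd.

    Requires at least ``min_peaks`` monitored peaks (default 3) so the spread
    of the per-peak estimates is meaningful; pass ``min_peaks=1`` to override.
    """
    grid = default_kd_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(titration.shifts) < min_peaks:
        raise ValidationError(
            f"need at least {min_peaks} peaks for a mean/sd estimate")
    fits = {k: _fit_peak(titration.ligand_conc, v, titration.protein_conc,
                         grid, min_signal)
            for k, v in sorted(titration.shifts.items())}
    kds = np.array([f.kd for f in fits.values()])
    return KdFit(per_peak=fits, kd_mean=float(np.mean(kds)),
                 kd_sd=float(np.std(kds, ddof=1)) if len(kds) > 1 else 0.0)


# ---------------------------------------------------------------------------
# additivity deconvolution
# ---------------------------------------------------------------------------

ADDITIVITY_COMPATIBLE = "compatible"
ADDITIVITY_UNEXPLAINED = "unexplained"


def additivity_check(mixture_mean_csp: float,
                     single_fragment_csps: list[float],
                     tolerance: float = 0.25,
                     noise_floor: float = 0.05) -> str:
    """Is the mixture CSP explained by the sum of its identified singles?

    Compatible iff |sum(singles) - mixture| <= max(tolerance * mixture,
    noise_floor); the absolute floor covers near-empty mixtures where the
    relative band collapses.  An unexplained residual suggests false
    negatives among the ligand-observed calls (re-testing is reported, not
    automated).
    """
    if not 0 < tolerance < 1:
        raise ValidationError("tolerance must lie in (0, 1)")
    if mixture_mean_csp == 0 and any(s != 0 for s in single_fragment_csps):
        raise ValidationError("zero mixture CSP with nonzero singles")
    residual = abs(sum(single_fragment_csps) - mixture_mean_csp)
    band = max(tolerance * mixture_mean_csp, noise_floor)
    return ADDITIVITY_COMPATIBLE if residual <= band else ADDITIVITY_UNEXPLAINED
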