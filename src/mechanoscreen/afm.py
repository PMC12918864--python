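"""AFM force-curve processing with the spherical-indenter Hertz model.

A force curve is the approach segment of a force-spectroscopy measurement:
piezo extension z (nm, increasing toward the cell) against cantilever force
F (pN, already converted from deflection via F = k*d). Fitting proceeds in
two stages, mirroring how such curves are handled in practice:

1. A coarse contact-point estimate from the intersection of a line fitted
   to the flat baseline region with a line fitted to the steep in-contact
   region.
2. Refinement by testing every sample within a window around that estimate
   as the contact point, fitting the Hertz model at each candidate, and
   keeping the candidate with minimal residual sum of squares over the
   curve.

The Hertz force for a rigid sphere of radius R indenting an elastic
half-space by depth delta is F = (4/3) * E_r * sqrt(R) * delta^(3/2),
where E_r is the reduced Young's modulus. Indentation is corrected for
cantilever compliance: delta = (z - z0) - F/k. Because F is linear in E_r,
the modulus at a fixed candidate contact point is obtained in closed form
by least squares of F against (4/3) sqrt(R) delta^(3/2) — the same optimum
a nonlinear fit would reach, without initialization concerns.

Units: z and R in nm, forces in pN, k in pN/nm, E_r in Pa. With those units
F_pN = (4/3) * E_r * sqrt(R_nm) * delta_nm^(3/2) * 1e-6.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .stats import GroupComparison, compare_groups

__all__ = [
    "ForceCurve",
    "HertzFit",
    "HertzParams",
    "ModulusComparison",
    "read_force_curve",
    "write_force_curve",
    "hertz_force",
    "estimate_contact_point",
    "refine_contact_point",
    "analyze_curve",
    "analyze_directory",
    "compare_modulus_groups",
    "young_modulus",
]

# F_pN = _HERTZ_UNIT * E_r_Pa * sqrt(R_nm) * delta_nm^1.5
_HERTZ_UNIT = 1e-6


@dataclass(frozen=True)
class ForceCurve:
    """Approach segment of one indentation measurement."""

    z: np.ndarray          # piezo extension, nm, strictly increasing
    force: np.ndarray      # pN
    k: float               # cantilever spring constant, pN/nm
    R: float               # probe radius, nm
    trigger: float = 10000.0   # max force used for fitting, pN (10 nN)
    name: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "force", f)
        if z.size != f.size or z.size < 3:
            raise ValueError("curve needs matching z/force arrays of >= 3 points")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite force values")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("k and R must be positive")

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.z)))


@dataclass(frozen=True)
class HertzFit:
    """Result of the two-stage contact-point / modulus fit."""

    E_r: float             # reduced Young's modulus, Pa
    z0: float              # contact point, nm
    rss: float             # residual sum of squares over evaluated points, pN^2
    r2: float
    n_fit: int             # points in the contact region used for the modulus
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not any(
            f in self.flags
            for f in ("negative-modulus", "degenerate-baseline", "poor-fit")
        )


@dataclass(frozen=True)
class HertzParams:
    """Tunable fit parameters; defaults suit 1024-point, ~4 um curves."""

    baseline_frac: float = 0.4
    contact_frac: float = 0.2
    window: int = 25           # refinement half-width, samples
    trigger: float | None = None   # pN; None = curve's own trigger
    max_window: int | None = None  # cap for automatic window widening


@dataclass(frozen=True)
class ModulusComparison:
    """Group comparison of fitted moduli plus the exceedance fraction.

    ``exceed_frac`` is the fraction of group b above max(group a) — the
    share of the perturbed population stiffer than the stiffest control.
    """

    comparison: GroupComparison
    max_a: float
    exceed_frac: float


def hertz_force(E_r: float, R: float, delta) -> np.ndarray | float:
    """Hertz force (pN) of a sphere of radius R (nm) at indentation delta (nm)."""
    if E_r <= 0 or R <= 0:
        raise ValueError("E_r and R must be positive")
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative indentation")
    out = _HERTZ_UNIT * (4.0 / 3.0) * E_r * math.sqrt(R) * d ** 1.5
    return float(out) if np.isscalar(delta) else out


def young_modulus(E_r: float, nu: float = 0.5) -> float:
    """Convert reduced modulus to Young's modulus, E = E_r * (1 - nu^2).

    Assumes a rigid probe; default Poisson ratio 0.5 (incompressible cell).
    """
    return E_r * (1.0 - nu**2)


# ---------------------------------------------------------------------------
# file I/O — TSV with '#'-prefixed metadata, columns z_nm / force_pN
# ---------------------------------------------------------------------------

def write_force_curve(curve: ForceCurve, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# k_pN_per_nm\t{curve.k!r}\n")
        fh.write(f"# R_nm\t{curve.R!r}\n")
        fh.write(f"# trigger_pN\t{curve.trigger!r}\n")
        fh.write("z_nm\tforce_pN\n")
        for z, f in zip(curve.z, curve.force):
            fh.write(f"{float(z)!r}\t{float(f)!r}\n")
    return path


def read_force_curve(
    path: str | Path,
    k: float | None = None,
    R: float | None = None,
    trigger: float | None = None,
) -> ForceCurve:
    """Read a force-curve TSV; header metadata may be overridden by arguments."""
    path = Path(path)
    meta: dict[str, float] = {}
    z_vals: list[float] = []
    f_vals: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) >= 2:
                    try:
                        meta[parts[0]] = float(parts[1])
                    except ValueError:
                        pass
                continue
            parts = line.split("\t")
            if parts[0] == "z_nm":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                z_vals.append(float(parts[0]))
                f_vals.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
    k = k if k is not None else meta.get("k_pN_per_nm")
    R = R if R is not None else meta.get("R_nm")
    trigger = trigger if trigger is not None else meta.get("trigger_pN", 10000.0)
    if k is None or R is None:
        raise ValueError(
            f"{path}: missing spring constant or probe radius "
            "(k_pN_per_nm / R_nm header lines, or pass k= / R=)"
        )
    z = np.asarray(z_vals)
    if z.size >= 2 and np.any(np.diff(z) <= 0):
        raise ValueError(f"{path}: z not strictly increasing")
    return ForceCurve(z=z, force=np.asarray(f_vals), k=k, R=R,
                      trigger=trigger, name=path.name)


# ---------------------------------------------------------------------------
# stage 1: line-intersection contact-point estimate
# ---------------------------------------------------------------------------

def _fit_line(z: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Least-squares slope/intercept."""
    slope, intercept = np.polyfit(z, f, 1)
    return float(slope), float(intercept)


def estimate_contact_point(
    curve: ForceCurve,
    baseline_frac: float = 0.4,
    contact_frac: float = 0.2,
) -> tuple[float, tuple[str, ...]]:
    """Coarse contact point from the baseline-line / contact-line intersection.

    Fits L1 to the first ``baseline_frac`` of samples (flat, off-surface) and
    L2 to the last ``contact_frac`` (in contact); returns the z of their
    intersection clamped to the curve range. Near-parallel lines raise a
    ``degenerate-baseline`` flag and fall back to the first sample exceeding
    the baseline by 3 baseline noise SDs.
    """
    if baseline_frac <= 0 or contact_frac <= 0 or baseline_frac + contact_frac > 1:
        raise ValueError("invalid baseline/contact fractions")
    n = curve.z.size
    nb = max(3, int(round(baseline_frac * n)))
    nc = max(3, int(round(contact_frac * n)))
    if nb + nc > n:
        raise ValueError("regions overlap: curve too short for the fractions")
    s1, b1 = _fit_line(curve.z[:nb], curve.force[:nb])
    s2, b2 = _fit_line(curve.z[-nc:], curve.force[-nc:])
    flags: list[str] = []
    force_scale = max(np.ptp(curve.force), 1.0)
    tol = 1e-9 * force_scale / max(np.ptp(curve.z), 1.0)
    if abs(s2 - s1) <= tol:
        flags.append("degenerate-baseline")
        resid = curve.force[:nb] - (s1 * curve.z[:nb] + b1)
        noise = float(resid.std(ddof=1)) if nb > 1 else 0.0
        above = curve.force - (s1 * curve.z + b1) > 3 * noise
        z0 = float(curve.z[np.argmax(above)]) if above.any() else float(curve.z[-1])
        return z0, tuple(flags)
    z0 = (b1 - b2) / (s2 - s1)
    lo, hi = float(curve.z[0]), float(curve.z[-1])
    if z0 < lo or z0 > hi:
        flags.append("boundary-contact")
        z0 = min(max(z0, lo), hi)
    return float(z0), tuple(flags)


# ---------------------------------------------------------------------------
# stage 2: candidate-sweep refinement
# ---------------------------------------------------------------------------

def _baseline_correct(curve: ForceCurve, baseline_frac: float) -> np.ndarray:
    n = curve.z.size
    nb = max(3, int(round(baseline_frac * n)))
    s, b = _fit_line(curve.z[:nb], curve.force[:nb])
    return curve.force - (s * curve.z + b)


def _fit_candidate(
    curve: ForceCurve,
    fc: np.ndarray,
    eval_mask: np.ndarray,
    j: int,
    trigger: float,
) -> tuple[float, float, int]:
    """Fit E_r with contact at sample j; return (E_r, rss, n_fit).

    rss is evaluated over all pre-trigger samples: the model predicts zero
    (baseline) before contact and the Hertz force after, making candidates
    directly comparable. Returns E_r <= 0 with rss = inf when the contact
    region carries no usable indentation.
    """
    z0 = curve.z[j]
    contact = eval_mask & (curve.z >= z0)
    delta = (curve.z - z0) - fc / curve.k
    use = contact & (delta > 0)
    n_fit = int(use.sum())
    if n_fit < 2:
        return 0.0, np.inf, n_fit
    x = _HERTZ_UNIT * (4.0 / 3.0) * math.sqrt(curve.R) * delta[use] ** 1.5
    denom = float(x @ x)
    if denom <= 0:
        return 0.0, np.inf, n_fit
    e_r = float(x @ fc[use]) / denom
    if e_r <= 0:
        return e_r, np.inf, n_fit
    pred = np.zeros(curve.z.size)
    pred[use] = e_r * x
    resid = fc[eval_mask] - pred[eval_mask]
    return e_r, float(resid @ resid), n_fit


def refine_contact_point(
    curve: ForceCurve,
    z0_est: float,
    window: int = 25,
    baseline_frac: float = 0.4,
    trigger: float | None = None,
) -> HertzFit:
    """Sweep candidate contact points around ``z0_est``; keep the min-rss fit.

    Every sample index within ``window`` of the estimate is tried as the
    contact point: the baseline line is subtracted, the compliance-corrected
    indentation delta = (z - z0) - F/k is formed, and E_r is fitted by least
    squares of F against (4/3) sqrt(R) delta^(3/2) over the pre-trigger
    contact region. Flags: ``boundary-window`` when the optimum sits at the
    window edge (widen the window), ``negative-modulus`` when no candidate
    yields E_r > 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    z = curve.z
    if not (z[0] <= z0_est <= z[-1]):
        raise ValueError("z0 estimate outside curve range")
    trig = curve.trigger if trigger is None else trigger
    fc = _baseline_correct(curve, baseline_frac)
    # evaluate rss over samples up to the first trigger crossing
    over = fc > trig
    last = int(np.argmax(over)) if over.any() else z.size
    eval_mask = np.zeros(z.size, dtype=bool)
    eval_mask[:max(last, 3)] = True

    j0 = int(np.argmin(np.abs(z - z0_est)))
    lo = max(0, j0 - window)
    hi = min(z.size - 1, j0 + window)
    best: tuple[float, float, int, int] | None = None  # (rss, E_r, n_fit, j)
    for j in range(lo, hi + 1):
        e_r, rss, n_fit = _fit_candidate(curve, fc, eval_mask, j, trig)
        if math.isfinite(rss) and (best is None or rss < best[0]):
            best = (rss, e_r, n_fit, j)
    flags: list[str] = []
    if best is None:
        return HertzFit(E_r=float("nan"), z0=float(z[j0]), rss=float("inf"),
                        r2=float("nan"), n_fit=0, flags=("negative-modulus",))
    rss, e_r, n_fit, j = best
    if j in (lo, hi) and lo != 0 and hi != z.size - 1:
        flags.append("boundary-window")
    elif j == 0 or j == z.size - 1:
        flags.append("boundary-contact")
    tss = float(np.sum((fc[eval_mask] - fc[eval_mask].mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    if r2 < 0.8:
        flags.append("poor-fit")
    return HertzFit(E_r=e_r, z0=float(z[j]), rss=rss, r2=r2,
                    n_fit=n_fit, flags=tuple(flags))


def analyze_curve(curve: ForceCurve, params: HertzParams = HertzParams()) -> HertzFit:
    """Full two-stage fit: coarse estimate, then refinement.

    The refinement window widens automatically (doubling, re-centred on the
    running optimum) while the minimum sits on the window edge, so a poor
    initial estimate still converges to the curve-wide rss minimum.
    """
    z0_est, est_flags = estimate_contact_point(
        curve, params.baseline_frac, params.contact_frac
    )
    window = params.window
    cap = params.max_window or curve.z.size
    fit = refine_contact_point(curve, z0_est, window, params.baseline_frac,
                               params.trigger)
    while "boundary-window" in fit.flags and window < cap:
        window = min(2 * window, cap)
        fit = refine_contact_point(curve, fit.z0, window, params.baseline_frac,
                                   params.trigger)
    extra = tuple(f for f in est_flags if f not in fit.flags)
    if extra:
        fit = replace(fit, flags=fit.flags + extra)
    return fit


def analyze_directory(
    paths: Iterable[str | Path],
    params: HertzParams = HertzParams(),
    k: float | None = None,
    R: float | None = None,
):
    """Batch-fit force-curve files; returns a pandas DataFrame summary."""
    import pandas as pd

    rows = []
    for p in paths:
        curve = read_force_curve(p, k=k, R=R)
        fit = analyze_curve(curve, params)
        rows.append(
            {
                "file": str(p),
                "E_r_Pa": fit.E_r,
                "z0_nm": fit.z0,
                "rss": fit.rss,
                "r2": fit.r2,
                "n_fit": fit.n_fit,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)


def compare_modulus_groups(
    moduli_a: Sequence[float], moduli_b: Sequence[float]
) -> ModulusComparison:
    """Compare two fitted-modulus populations (control a vs perturbed b).

    Reports the Welch and Brown–Forsythe tests plus the fraction of group b
    exceeding the maximum of group a.
    """
    a = np.asarray(moduli_a, dtype=float)
    b = np.asarray(moduli_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 unflagged fits per group")
    comp = compare_groups(a, b)
    max_a = float(a.max())
    return ModulusComparison(
        comparison=comp, max_a=max_a, exceed_frac=float((b > max_a).mean())
    )
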