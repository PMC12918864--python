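"""Synthetic inputs with known ground truth for every pipeline stage.

The screen this package analyses deposits no raw data, so each consumer
module is exercised against generated inputs that mirror the statistical
structure the analysis assumes:

- a Brunello-like guide library (unique 20-nt protospacers, ~4 guides/gene);
- inlet/outlet guide count matrices with negative-binomial sequencing noise,
  log-normal library skew, and designated genes whose knockouts carry
  per-outlet sorting-weight multipliers;
- amplicon FASTQ reads of the form vector-anchor + protospacer + filler;
- Hertzian force curves with baseline tilt and Gaussian force noise, with
  the indentation/deflection balance solved self-consistently;
- ridged-device cell tracks with per-ridge deflections and dwell times tied
  to a latent per-cell stiffness score.

Every generator is a pure function of its arguments including the seed, and
each returns (or writes alongside its output) the ground truth needed for
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .afm import ForceCurve, hertz_force
from .tracks import RidgeGeometry, TRACK_COLUMNS

__all__ = [
    "ANCHOR",
    "ScreenDesign",
    "ScreenTruth",
    "DeflectionModel",
    "make_guide_library",
    "write_guide_library",
    "read_guide_library",
    "make_screen_truth",
    "simulate_screen_counts",
    "write_screen_fastq",
    "simulate_force_curve",
    "simulate_tracks",
]

# 19-nt prefix of the vector sequence printed ahead of the protospacer in
# amplicon reads (trailing NNN wildcard positions dropped).
ANCHOR = "TTGTGGAAAGGACGAAACA"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScreenDesign:
    """Sample layout of one screen: one inlet plus >= 1 outlet conditions."""

    inlet: str = "inlet"
    outlets: tuple[str, ...] = ("outlet4",)
    replicates: int = 3

    def __post_init__(self) -> None:
        if not self.outlets:
            raise ValueError("need at least one outlet condition")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def conditions(self) -> tuple[str, ...]:
        return (self.inlet, *self.outlets)

    @property
    def samples(self) -> list[tuple[str, str, int]]:
        """(sample_name, condition, replicate) triples."""
        return [
            (f"{cond}_r{r}", cond, r)
            for cond in self.conditions
            for r in range(1, self.replicates + 1)
        ]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c, _ in self.samples if c == condition]


@dataclass(frozen=True)
class ScreenTruth:
    """Generative ground truth of one simulated screen.

    ``abundances`` is the relative inlet abundance per guide (a simplex over
    the library rows); ``effect_map`` maps gene -> {outlet: multiplier}
    where the multiplier (>= 0, 1 = neutral) scales that gene's sorting
    weight into the outlet before renormalisation; ``dispersion`` is the
    guide-level negative-binomial overdispersion (variance = m + a m^2).
    """

    abundances: np.ndarray
    effect_map: Mapping[str, Mapping[str, float]]
    dispersion: float
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", a)
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if np.any(a < 0):
            raise ValueError("abundances must be non-negative")
        for gene, per_outlet in self.effect_map.items():
            for outlet, mult in per_outlet.items():
                if not np.isfinite(mult) or mult < 0:
                    raise ValueError(f"bad multiplier {mult} for {gene}/{outlet}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def multiplier(self, gene: str, outlet: str) -> float:
        return float(self.effect_map.get(gene, {}).get(outlet, 1.0))


@dataclass(frozen=True)
class DeflectionModel:
    """Per-ridge deflection/dwell statistics as a function of latent stiffness.

    Each cell draws a latent stiffness score s ~ N(0, 1). At every ridge it
    gains Δy ~ N(dy_mean + dy_gain * s, dy_sd) μm and dwells
    max(0, N(dwell_mean + dwell_gain * s, dwell_sd)) seconds in the window.
    """

    dy_mean: float = 0.0
    dy_sd: float = 0.0
    dy_gain: float = 0.0
    dwell_mean: float = 0.01
    dwell_sd: float = 0.0
    dwell_gain: float = 0.0


# ---------------------------------------------------------------------------
# guide library
# ---------------------------------------------------------------------------

def make_guide_library(
    n_genes: int,
    guides_per_gene: int,
    protospacer_length: int = 20,
    seed: int = 0,
    max_retry_rounds: int = 100,
) -> pd.DataFrame:
    """Random guide library: unique protospacers, genes GENE0001, GENE0002, ...

    Columns: guide_id, gene, protospacer. Guide ids are ``<gene>_g<i>``.
    Deterministic for a given seed; raises if unique protospacers cannot be
    found within ``max_retry_rounds`` redraw rounds (only conceivable when
    4^length is close to the library size).
    """
    if n_genes < 1 or guides_per_gene < 1:
        raise ValueError("n_genes and guides_per_gene must be positive")
    if protospacer_length < 1:
        raise ValueError("protospacer_length must be >= 1")
    n = n_genes * guides_per_gene
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    rounds = 0
    while len(seen) < n:
        need = n - len(seen)
        draw = rng.integers(0, 4, size=(need, protospacer_length))
        for row in _BASES[draw]:
            s = "".join(row)
            if s not in seen:
                seen[s] = None
        rounds += 1
        if rounds > max_retry_rounds:
            raise RuntimeError(
                f"could not draw {n} unique protospacers of length "
                f"{protospacer_length} in {max_retry_rounds} rounds"
            )
    protospacers = list(seen)[:n]
    width = max(4, len(str(n_genes)))
    genes = [f"GENE{i + 1:0{width}d}" for i in range(n_genes)]
    records = []
    idx = 0
    for gene in genes:
        for g in range(1, guides_per_gene + 1):
            records.append((f"{gene}_g{g}", gene, protospacers[idx]))
            idx += 1
    return pd.DataFrame(records, columns=["guide_id", "gene", "protospacer"])


def write_guide_library(library: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    library[["guide_id", "gene", "protospacer"]].to_csv(path, index=False)
    return path


def read_guide_library(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("guide_id", "gene", "protospacer") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["protospacer"] = df["protospacer"].str.upper()
    bad = ~df["protospacer"].str.fullmatch("[ACGT]+")
    if bad.any():
        raise ValueError(f"{path}: non-ACGT protospacers at rows {list(df.index[bad][:5])}")
    return df


# ---------------------------------------------------------------------------
# screen counts
# ---------------------------------------------------------------------------

def make_screen_truth(
    library: pd.DataFrame,
    effect_map: Mapping[str, Mapping[str, float]] | None = None,
    dispersion: float = 0.1,
    abundance_sigma: float = 0.5,
    seed: int = 0,
) -> ScreenTruth:
    """Draw inlet abundances (log-normal, then normalised) and package truth.

    The log-normal skew (sigma defaults to 0.5) mimics the uneven guide
    representation of real libraries so that the Gini QC has signal even in
    the inlet.
    """
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(library))
    return ScreenTruth(
        abundances=raw / raw.sum(),
        effect_map=dict(effect_map or {}),
        dispersion=dispersion,
        seed=seed,
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with variance m + alpha m^2; Poisson in the alpha -> 0 limit."""
    mean = np.clip(mean, 0.0, None)
    if alpha < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen_counts(
    library: pd.DataFrame,
    design: ScreenDesign,
    truth: ScreenTruth,
    depth: float,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate the guide x sample count matrix for one screen.

    Inlet counts ~ NB(depth * abundance_g, dispersion). For each outlet the
    expected abundance is the inlet abundance times the gene's sorting
    multiplier, renormalised to a simplex, then NB-sampled at the same
    depth. ``depth`` is total reads per sample divided by... rather, the
    expected total reads per sample: per-guide mean = depth * abundance.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if len(library) == 0:
        raise ValueError("empty library")
    if len(truth.abundances) != len(library):
        raise ValueError("truth abundances do not align with library")
    rng = np.random.default_rng(truth.seed)
    genes = library["gene"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    for sample, cond, _rep in design.samples:
        if cond == design.inlet:
            expected = truth.abundances
        else:
            mult = np.array([truth.multiplier(g, cond) for g in genes])
            weighted = truth.abundances * mult
            total = weighted.sum()
            if total <= 0:
                raise ValueError(f"all sorting weights vanish in {cond}")
            expected = weighted / total
        cols[sample] = _nb_sample(rng, depth * expected, truth.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(library["guide_id"], name="guide_id"))
    return counts, truth


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_screen_fastq(
    library: pd.DataFrame,
    counts: pd.DataFrame,
    outdir: str | Path,
    anchor: str = ANCHOR,
    read_length: int = 75,
    seed: int = 0,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Write one FASTQ per sample: reads are anchor + protospacer + filler.

    Per-sample record totals equal the count column sums exactly; quality is
    a constant 'I' string (quality is not used downstream). Returns
    {sample: path}.
    """
    proto_len = int(library["protospacer"].str.len().iloc[0])
    if read_length < len(anchor) + proto_len:
        raise ValueError(
            f"read_length {read_length} shorter than anchor+protospacer "
            f"({len(anchor) + proto_len})"
        )
    if not set(counts.index) <= set(library["guide_id"]):
        raise ValueError("count matrix contains guides absent from the library")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proto = library.set_index("guide_id")["protospacer"]
    fill_len = read_length - len(anchor) - proto_len
    qual = "I" * read_length
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    import gzip as _gzip

    for sample in counts.columns:
        path = outdir / (f"{sample}.fastq.gz" if gzip_output else f"{sample}.fastq")
        opener = _gzip.open if gzip_output else open
        with opener(path, "wt") as fh:
            i = 0
            for guide_id, c in counts[sample].items():
                c = int(c)
                if c == 0:
                    continue
                stem = anchor + proto[guide_id]
                fillers = _BASES[rng.integers(0, 4, size=(c, fill_len))] if fill_len else None
                for j in range(c):
                    filler = "".join(fillers[j]) if fill_len else ""
                    fh.write(f"@{sample}:{i}\n{stem}{filler}\n+\n{qual}\n")
                    i += 1
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

def simulate_force_curve(
    E_r: float,
    z0: float,
    R: float = 3660.0,
    k: float = 30.0,
    baseline_slope: float = 0.0,
    noise_sd: float = 0.0,
    n_points: int = 1024,
    z_range: tuple[float, float] = (0.0, 4000.0),
    trigger: float = 10000.0,
    seed: int = 0,
) -> tuple[ForceCurve, dict[str, float]]:
    """Forward-simulate a Hertzian approach curve.

    For z < z0 the force is the baseline (slope * z + noise); for z >= z0
    the Hertz force is added, with the indentation solved self-consistently
    against the cantilever deflection d = F/k: delta = (z - z0) - d and
    F = (4/3) E_r sqrt(R) delta^(3/2). Defaults reflect the measurement
    setup: 7.32 μm polystyrene bead (R = 3660 nm), k ≈ 30 pN/nm, 10 nN
    force trigger.
    """
    if E_r <= 0 or R <= 0 or k <= 0:
        raise ValueError("E_r, R and k must be positive")
    lo, hi = z_range
    if not (lo <= z0 <= hi):
        raise ValueError("z0 outside z_range")
    rng = np.random.default_rng(seed)
    z = np.linspace(lo, hi, n_points)
    c = 1e-6 * (4.0 / 3.0) * E_r * math.sqrt(R)
    force = np.zeros(n_points)
    for i, zi in enumerate(z):
        if zi < z0:
            continue
        span = zi - z0
        if span == 0:
            continue

        def balance(F: float) -> float:
            delta = span - F / k
            return F - (c * delta**1.5 if delta > 0 else 0.0)

        # F is bracketed by 0 and the rigid-contact limit k*span
        force[i] = brentq(balance, 0.0, k * span, xtol=1e-9 * max(1.0, k * span))
    baseline = baseline_slope * z
    if noise_sd > 0:
        baseline = baseline + rng.normal(0.0, noise_sd, size=n_points)
    curve = ForceCurve(z=z, force=force + baseline, k=k, R=R, trigger=trigger,
                       name=f"synthetic_Er{E_r:g}_seed{seed}")
    params = {"E_r": E_r, "z0": z0, "R": R, "k": k,
              "baseline_slope": baseline_slope, "noise_sd": noise_sd}
    return curve, params


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def simulate_tracks(
    geometry: RidgeGeometry,
    n_cells: int,
    model: DeflectionModel,
    fps: float = 2500.0,
    pos_noise: float = 0.0,
    speed: float = 5000.0,
    y_start: float = 150.0,
    lead: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ridged-device trajectories sampled at the camera frame rate.

    Each cell advances in +x at ``speed`` μm/s between ridges. Within each
    ridge window it spends its drawn dwell time (floored at the traversal
    time and at a few frame intervals) while its along-flow distance u ramps
    from -w/2 to +w/2; the drawn Δy is gained linearly over the interior of
    the window, padded by 1.5 frame intervals at each end so that the first
    and last sampled in-window frames carry the pre- and post-ridge y
    exactly. Positions are sampled at ``fps`` with isotropic Gaussian noise
    of SD ``pos_noise`` μm. Returns (track table, truth table); the truth
    table holds one row per (cell, ridge) with the true Δy and realized
    dwell, plus each cell's latent stiffness score.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if geometry.n_ridges < 1:
        raise ValueError("geometry has no ridges")
    rng = np.random.default_rng(seed)
    n_r = geometry.n_ridges
    half = geometry.width / 2.0
    tan = geometry.tan_angle
    frames_rows = []
    truth_rows = []
    for cell in range(n_cells):
        s = rng.normal()
        dys = rng.normal(model.dy_mean + model.dy_gain * s, model.dy_sd, size=n_r) \
            if model.dy_sd > 0 else np.full(n_r, model.dy_mean + model.dy_gain * s)
        dwells = rng.normal(model.dwell_mean + model.dwell_gain * s,
                            model.dwell_sd, size=n_r) \
            if model.dwell_sd > 0 else np.full(n_r, model.dwell_mean + model.dwell_gain * s)
        dwells = np.clip(dwells, 0.0, None)
        pad = 1.5 / fps
        # piecewise-linear breakpoints (t, x, y)
        x = geometry.ridge_x[0] + (y_start - geometry.y_ref) * tan - half - lead
        y = y_start
        t = 0.0
        bx, by, bt = [x], [y], [t]
        for i in range(n_r):
            dy = dys[i]
            entry = geometry.ridge_x[i] + (y - geometry.y_ref) * tan - half
            if entry > x:
                t += (entry - x) / speed
                x = entry
                bx.append(x); by.append(y); bt.append(t)
            # window traversal: u ramps -w/2 -> +w/2; y ramps over the
            # interior, padded so sampled edge frames see the flat y
            traverse = (geometry.width + abs(dy) * abs(tan)) / speed
            dt_win = max(dwells[i], traverse, 2.0 * pad + 1.0 / fps)
            dwells[i] = dt_win  # record realized dwell as truth

            def x_of(u: float, yy: float, ridge: int = i) -> float:
                return geometry.ridge_x[ridge] + (yy - geometry.y_ref) * tan + u

            du_dt = geometry.width / dt_win
            for seg_t, seg_y in (
                (pad, y),                      # flat y, u advances
                (dt_win - pad, y + dy),        # y ramp done by exit - pad
                (dt_win, y + dy),              # flat y to the exit
            ):
                u = -half + du_dt * seg_t
                bt.append(t + seg_t)
                by.append(seg_y)
                bx.append(x_of(u, seg_y))
            t += dt_win
            y += dy
            x = x_of(half, y)
        # run-out past the last ridge
        t += lead / speed
        x += lead
        bx.append(x); by.append(y); bt.append(t)
        n_frames = int(math.floor(t * fps)) + 1
        ft = np.arange(n_frames) / fps
        fx = np.interp(ft, bt, bx)
        fy = np.interp(ft, bt, by)
        if pos_noise > 0:
            fx = fx + rng.normal(0.0, pos_noise, size=n_frames)
            fy = fy + rng.normal(0.0, pos_noise, size=n_frames)
        frames_rows.append(
            pd.DataFrame(
                {
                    "TRACK_ID": cell,
                    "FRAME": np.arange(n_frames),
                    "POSITION_X": fx,
                    "POSITION_Y": fy,
                }
            )
        )
        for i in range(n_r):
            truth_rows.append((cell, s, i + 1, float(dys[i]), float(dwells[i])))
    tracks = pd.concat(frames_rows, ignore_index=True)[TRACK_COLUMNS]
    truth = pd.DataFrame(
        truth_rows, columns=["TRACK_ID", "stiffness", "ridge", "dy_true", "dwell_true"]
    )
    return tracks, truth
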