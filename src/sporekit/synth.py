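"""Synthetic ground-truth generators for spore phenotyping assays.

Every downstream stage of the toolkit (trace extraction, changepoint
fitting, plate-reader germination metrics, survival fitting, homolog
census) is validated against data produced here, because the wet-lab
assays it models deposit no raw data.  Each generator is a pure function
of its parameters and a seed, and returns the ground truth alongside the
simulated observation so recovery can be scored exactly.

The single-spore intensity model is piecewise linear in four phases:

* lag: the normalized phase-contrast intensity decays slowly from 1 with
  slope ``leak_slope`` (CaDPA leaking out before commitment),
* rapid release: linear drop from ``i_lag`` (intensity at ``t_lag``) to
  ``i_release`` at ``t_release``,
* cortex lysis: linear drop from ``i_release`` to 0 at ``t_lys``,
* after lysis: 0.

Non-germinating spores keep intensity 1 throughout.  Times are minutes
from the first frame; frame ``k`` is at ``k * frame_interval``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SporeTruth",
    "PopulationParams",
    "ImagingParams",
    "DistSpec",
    "generate_truth",
    "render_stack",
    "generate_population_fluorescence",
    "generate_survival_counts",
    "generate_protein_set",
    "mutate_from_prototype",
    "intensity_fraction",
    "released_fraction",
    "YETF_PROTOTYPE",
    "DUF2_PROTOTYPE",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _make_prototype(length: int, seed: int) -> str:
    rng = np.random.Generator(np.random.PCG64(seed))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# Synthetic stand-ins for the YetF (231 aa) and 2Duf (286 aa) reference
# sequences: deterministic random-residue prototypes, NOT the biological
# sequences.  They anchor the mutation-based generator and the census
# aligner's query set.
YETF_PROTOTYPE = _make_prototype(231, 20_210_231)
DUF2_PROTOTYPE = _make_prototype(286, 20_210_286)


# ---------------------------------------------------------------------------
# distribution plumbing


@dataclass(frozen=True)
class DistSpec:
    """A named positive-support distribution family plus its parameters.

    Supported families: ``lognormal`` (meanlog, sdlog), ``gamma`` (shape,
    scale), ``uniform`` (low, high), ``constant`` (value).
    """

    family: str
    params: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(p["meanlog"], p["sdlog"], size=n)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=n)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        if self.family == "constant":
            return np.full(n, float(p["value"]))
        raise ValueError(f"unknown distribution family: {self.family!r}")


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass
class PopulationParams:
    """Population-level heterogeneity model for a field of spores.

    Defaults emulate a healthy, optimally heat-activated population:
    most spores germinate, lag times are right-skewed around ~10 min,
    rapid CaDPA release takes a couple of minutes and cortex lysis a few
    more, with a small slow leak during the lag.
    """

    n_spores: int = 300
    frac_germinating: float = 0.9
    t_lag_dist: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"meanlog": np.log(10.0), "sdlog": 0.3})
    )
    dt_release_dist: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"meanlog": np.log(2.0), "sdlog": 0.3})
    )
    dt_lys_dist: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"meanlog": np.log(6.0), "sdlog": 0.3})
    )
    leak_slope_range: tuple[float, float] = (0.0, 0.008)
    i_release_range: tuple[float, float] = (0.25, 0.55)
    seed: int = 0

    def validate(self) -> None:
        if self.n_spores < 1:
            raise ValueError("n_spores must be >= 1")
        if not 0.0 <= self.frac_germinating <= 1.0:
            raise ValueError("frac_germinating must be in [0, 1]")
        lo, hi = self.leak_slope_range
        if lo < 0 or hi < lo:
            raise ValueError("leak_slope_range must be 0 <= lo <= hi")
        lo, hi = self.i_release_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("i_release_range must lie inside (0, 1)")


@dataclass
class ImagingParams:
    """Geometry and noise of the simulated phase-contrast recording.

    Frame geometry (1340 x 1024) and 12-bit depth follow the CCD camera
    used for the real recordings; 0.25 min interval is 1 frame / 15 s.
    Background and amplitude defaults emulate phase-bright spores on a
    dim background, so a germinating spore's 20x20-window mean drops by
    well over half of its initial value — as in the real assay, where
    the window covers the whole phase-contrast image of the spore.
    """

    frame_interval: float = 0.25
    duration: float = 60.0
    width: int = 1340
    height: int = 1024
    bit_depth: int = 12
    spore_radius: int = 4
    background_level: float = 150.0
    spore_amplitude: float = 2400.0
    noise_sd: float = 0.0
    min_separation: int = 20

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if self.spore_amplitude <= 0:
            raise ValueError("spore_amplitude must be > 0")
        if self.min_separation < 2 * self.spore_radius:
            raise ValueError("min_separation must be >= 2 * spore_radius")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration / self.frame_interval)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    # centers must leave room for the disc and the 20x20 trace window
    @property
    def margin(self) -> int:
        return self.spore_radius + 10


@dataclass
class SporeTruth:
    """Ground truth for one simulated spore.

    Kinetic fields are NaN for non-germinating spores.  ``i_lag`` is the
    normalized intensity when rapid release starts (1 - leak_slope*t_lag);
    ``i_release`` the intensity when CaDPA release completes.
    """

    spore_id: str
    x: int
    y: int
    germinates: bool
    t_lag: float = float("nan")
    t_release: float = float("nan")
    t_lys: float = float("nan")
    leak_slope: float = 0.0
    i_release: float = float("nan")

    @property
    def i_lag(self) -> float:
        if not self.germinates:
            return float("nan")
        return 1.0 - self.leak_slope * self.t_lag


# ---------------------------------------------------------------------------
# single-spore piecewise model


def intensity_fraction(spore: SporeTruth, t: np.ndarray) -> np.ndarray:
    """Normalized intensity of one spore at times ``t`` (minutes).

    Piecewise linear: lag-leak, rapid release, lysis, then zero.
    Non-germinating spores stay at 1.
    """
    t = np.asarray(t, dtype=float)
    if not spore.germinates:
        return np.ones_like(t)
    knots_t = [0.0, spore.t_lag, spore.t_release, spore.t_lys]
    knots_v = [1.0, spore.i_lag, spore.i_release, 0.0]
    return np.interp(t, knots_t, knots_v, left=1.0, right=0.0)


def released_fraction(spore: SporeTruth, t: np.ndarray) -> np.ndarray:
    """Fraction of a spore's CaDPA released by time ``t``.

    Slow leak during the lag, then linear completion over the rapid
    release phase; lysis releases no further CaDPA.  Non-germinators
    release nothing.
    """
    t = np.asarray(t, dtype=float)
    if not spore.germinates:
        return np.zeros_like(t)
    leaked_at_lag = spore.leak_slope * spore.t_lag
    knots_t = [0.0, spore.t_lag, spore.t_release]
    knots_v = [0.0, leaked_at_lag, 1.0]
    return np.interp(t, knots_t, knots_v, left=0.0, right=1.0)


# ---------------------------------------------------------------------------
# generators


def generate_truth(
    params: PopulationParams,
    imaging: ImagingParams | None = None,
) -> list[SporeTruth]:
    """Sample a population of spores with known kinetics and positions.

    Centers are dart-thrown inside the frame (margin wide enough for the
    disc and the 20x20 analysis window) with all pairwise distances
    >= ``imaging.min_separation``.  The germinating subpopulation is an
    exact count ``round(frac_germinating * n_spores)``; which spores
    germinate is randomized.

    Raises ``ValueError`` when the frame cannot hold ``n_spores`` at the
    required separation.
    """
    params.validate()
    imaging = imaging if imaging is not None else ImagingParams()
    imaging.validate()
    rng = np.random.Generator(np.random.PCG64(params.seed))
    n = params.n_spores

    sep = imaging.min_separation
    m = imaging.margin
    lo_x, hi_x = m, imaging.width - m
    lo_y, hi_y = m, imaging.height - m
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("frame too small for margins")
    # capacity bound: a packing at pitch `sep` cannot beat the grid count
    cap = (1 + (hi_x - lo_x) // sep) * (1 + (hi_y - lo_y) // sep)
    if n > cap:
        raise ValueError(
            f"cannot place {n} spores at min_separation={sep} in a "
            f"{imaging.width}x{imaging.height} frame (capacity ~{cap})"
        )
    xs = np.empty(n, dtype=int)
    ys = np.empty(n, dtype=int)
    placed = 0
    attempts = 0
    max_attempts = 20_000 * max(n, 1)
    while placed < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"failed to place {n} spores at min_separation={sep} "
                f"(placed {placed}); frame too crowded"
            )
        attempts += 1
        x = int(rng.integers(lo_x, hi_x))
        y = int(rng.integers(lo_y, hi_y))
        if placed:
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            if d2.min() < sep * sep:
                continue
        xs[placed] = x
        ys[placed] = y
        placed += 1

    n_germ = int(round(params.frac_germinating * n))
    germ = np.zeros(n, dtype=bool)
    germ[rng.permutation(n)[:n_germ]] = True

    t_lag = params.t_lag_dist.sample(rng, n)
    dt_rel = params.dt_release_dist.sample(rng, n)
    dt_lys = params.dt_lys_dist.sample(rng, n)
    leak = rng.uniform(*params.leak_slope_range, size=n)
    # keep i_lag = 1 - leak*t_lag strictly positive and above i_release
    leak = np.minimum(leak, 0.9 / np.maximum(t_lag, 1e-9))
    i_rel = rng.uniform(*params.i_release_range, size=n)
    i_lag = 1.0 - leak * t_lag
    i_rel = np.minimum(i_rel, 0.9 * i_lag)
    # the phases must be distinct to be phases at all: rapid release is
    # at least twice as steep as cortex lysis, else t_release is not
    # identifiable from the trace (the two segments become collinear)
    slope_bound = i_lag * dt_lys / (dt_lys + 2.0 * dt_rel)
    i_rel = np.minimum(i_rel, 0.95 * slope_bound)

    out: list[SporeTruth] = []
    for i in range(n):
        if germ[i]:
            out.append(
                SporeTruth(
                    spore_id=f"spore_{i:04d}",
                    x=int(xs[i]),
                    y=int(ys[i]),
                    germinates=True,
                    t_lag=float(t_lag[i]),
                    t_release=float(t_lag[i] + dt_rel[i]),
                    t_lys=float(t_lag[i] + dt_rel[i] + dt_lys[i]),
                    leak_slope=float(leak[i]),
                    i_release=float(i_rel[i]),
                )
            )
        else:
            out.append(
                SporeTruth(
                    spore_id=f"spore_{i:04d}", x=int(xs[i]), y=int(ys[i]), germinates=False
                )
            )
    return out


def truth_roster(truth: Sequence[SporeTruth], truncated_after: float | None = None) -> pd.DataFrame:
    """Tabulate ground truth; ``truncated`` flags spores whose lysis
    outlasts the recording (``truncated_after`` = recording duration)."""
    rows = []
    for s in truth:
        rows.append(
            {
                "spore_id": s.spore_id,
                "x": s.x,
                "y": s.y,
                "germinates": s.germinates,
                "t_lag": s.t_lag,
                "t_release": s.t_release,
                "t_lys": s.t_lys,
                "leak_slope": s.leak_slope,
                "i_lag": s.i_lag,
                "i_release": s.i_release,
                "truncated": bool(
                    truncated_after is not None
                    and s.germinates
                    and s.t_lys > truncated_after
                ),
            }
        )
    return pd.DataFrame(rows)


def render_stack(
    truth: Sequence[SporeTruth],
    imaging: ImagingParams,
    seed: int = 0,
    dtype=np.float64,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a time-lapse stack (frames, H, W) plus its roster table.

    Each spore is a hard disc of radius ``spore_radius`` whose amplitude
    above background follows the piecewise intensity model; i.i.d.
    Gaussian pixel noise of sd ``noise_sd`` is added and values clipped
    to the bit-depth range.  Frames stay floating point so that the
    noise-free stack reproduces the model to machine precision.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    imaging.validate()
    m = imaging.margin
    for s in truth:
        if not (m <= s.x < imaging.width - m and m <= s.y < imaging.height - m):
            raise ValueError(f"{s.spore_id} center ({s.x},{s.y}) too close to frame edge")
    xs = np.array([s.x for s in truth])
    ys = np.array([s.y for s in truth])
    if len(truth) > 1:
        d2 = (xs[:, None] - xs[None, :]) ** 2 + (ys[:, None] - ys[None, :]) ** 2
        np.fill_diagonal(d2, np.iinfo(np.int64).max)
        if d2.min() < (2 * imaging.spore_radius) ** 2:
            raise ValueError("overlapping spore discs in truth")

    times = imaging.times
    n_frames = imaging.n_frames
    rng = np.random.Generator(np.random.PCG64(seed))

    # disc offsets once
    r = imaging.spore_radius
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = dy * dy + dx * dx <= r * r
    off_y = dy[disc]
    off_x = dx[disc]

    amp = np.empty((len(truth), n_frames))
    for i, s in enumerate(truth):
        amp[i] = intensity_fraction(s, times)

    stack = np.empty((n_frames, imaging.height, imaging.width), dtype=dtype)
    for k in range(n_frames):
        frame = np.full((imaging.height, imaging.width), imaging.background_level, dtype=dtype)
        for i, s in enumerate(truth):
            frame[s.y + off_y, s.x + off_x] += imaging.spore_amplitude * amp[i, k]
        if imaging.noise_sd > 0:
            frame += rng.normal(0.0, imaging.noise_sd, size=frame.shape)
        np.clip(frame, 0.0, imaging.max_value, out=frame)
        stack[k] = frame

    roster = truth_roster(truth, truncated_after=imaging.duration)
    return stack, roster


def generate_population_fluorescence(
    truth: Sequence[SporeTruth],
    total_signal: float,
    baseline: float = 0.0,
    frame_interval: float = 0.5,
    duration: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "synthetic",
):
    """Simulate a Tb-DPA plate-reader germination curve for a population.

    Each spore contributes ``(total_signal / n) * r_i(t)`` where ``r_i``
    is its released-CaDPA fraction; non-germinators contribute nothing,
    so the plateau expectation is ``baseline + total_signal * f_germ``.
    ``total_cadpa_signal`` on the returned curve is the boiled-control
    reading for the same aliquot, ``baseline + total_signal``.
    """
    from .plate import PopulationCurve  # local import: plate does not import synth

    if total_signal <= 0:
        raise ValueError("total_signal must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not truth:
        raise ValueError("truth must be non-empty")
    times = np.arange(0.0, duration + 1e-9, frame_interval)
    n = len(truth)
    released = np.zeros_like(times)
    for s in truth:
        released += released_fraction(s, times)
    rfu = baseline + (total_signal / n) * released
    if noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        rfu = rfu + rng.normal(0.0, noise_sd, size=rfu.shape)
    return PopulationCurve(
        condition=condition,
        times=times,
        rfu=rfu,
        baseline=baseline,
        total_cadpa_signal=baseline + total_signal,
    )


def generate_survival_counts(
    n0: float,
    d_value: float,
    times: Sequence[float],
    dilutions: Sequence[int],
    spot_volume: float = 0.01,
    replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate colony counts from the dilution-spotting killing assay.

    First-order inactivation ``N(t) = n0 * 10**(-t / d_value)`` (CFU/mL);
    each spotted aliquot at dilution ``10**-d`` yields a Poisson count
    with mean ``N(t) * spot_volume * 10**-d``.  Duplicate 10 uL spots
    (replicates=2, spot_volume=0.01 mL) mirror the bench protocol.
    """
    if d_value <= 0:
        raise ValueError("d_value must be > 0")
    if spot_volume <= 0:
        raise ValueError("spot_volume must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    times = np.asarray(list(times), dtype=float)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    rng = np.random.Generator(np.random.PCG64(seed))
    rows = []
    for t in times:
        titer = n0 * 10.0 ** (-t / d_value)
        for d in dilutions:
            mean = titer * spot_volume * 10.0 ** (-d)
            counts = rng.poisson(mean, size=replicates)
            row = {
                "time_min": float(t),
                "dilution_exponent": int(d),
                "spot_volume_ml": spot_volume,
            }
            for j, c in enumerate(counts, start=1):
                row[f"count_rep{j}"] = int(c)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protein sets


def mutate_from_prototype(
    prototype: str,
    identity: float,
    target_length: int,
    rng: np.random.Generator,
) -> str:
    """Derive a sequence at a controlled identity from a prototype.

    Exactly ``round((1 - identity) * len(prototype))`` positions are
    substituted (each with a different residue), then the C-terminus is
    trimmed or extended with random residues to reach ``target_length``.
    Terminal indels do not count against identity as measured by the
    census aligner (terminal-gap columns are excluded there).
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    seq = list(prototype)
    n_mut = int(round((1.0 - identity) * len(seq)))
    if n_mut:
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        for p in pos:
            choices = [a for a in AMINO_ACIDS if a != seq[p]]
            seq[p] = choices[int(rng.integers(len(choices)))]
    if target_length < len(seq):
        seq = seq[:target_length]
    elif target_length > len(seq):
        extra = rng.choice(list(AMINO_ACIDS), size=target_length - len(seq))
        seq = seq + list(extra)
    return "".join(seq)


def generate_protein_set(
    n_yetf_like: int,
    n_2duf_like: int,
    n_other: int,
    seed: int = 0,
    identity: float = 0.70,
    n_species: int = 7,
):
    """Generate labeled protein records for the census round-trip.

    YetF-like records are mutated copies of the YetF prototype with
    lengths in 210-253; 2Duf-like from the 2Duf prototype with lengths
    in 285-290; "other" records are unrelated random sequences whose
    lengths fall outside both windows.  Returns ``(records, labels)``
    where ``labels[record.id]`` is the true class.
    """
    from .census import ProteinRecord  # census does not import synth

    if min(n_yetf_like, n_2duf_like, n_other) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    records = []
    labels: dict[str, str] = {}
    idx = 0

    def add(seq: str, label: str) -> None:
        nonlocal idx
        rid = f"prot_{idx:03d}"
        species = f"Species_{idx % n_species:02d}"
        records.append(ProteinRecord(id=rid, species=species, sequence=seq))
        labels[rid] = label
        idx += 1

    for _ in range(n_yetf_like):
        length = int(rng.integers(210, 254))
        add(mutate_from_prototype(YETF_PROTOTYPE, identity, length, rng), "YetF-like")
    for _ in range(n_2duf_like):
        length = int(rng.integers(285, 291))
        add(mutate_from_prototype(DUF2_PROTOTYPE, identity, length, rng), "2Duf-like")
    for _ in range(n_other):
        if rng.random() < 0.5:
            length = int(rng.integers(100, 191))
        else:
            length = int(rng.integers(300, 401))
        add("".join(rng.choice(list(AMINO_ACIDS), size=length)), "unclassified")
    return records, labels


# ---------------------------------------------------------------------------
# config (de)serialization for the CLI


def population_params_from_dict(d: dict) -> PopulationParams:
    kw = dict(d)
    for key in ("t_lag_dist", "dt_release_dist", "dt_lys_dist"):
        if key in kw:
            kw[key] = DistSpec(kw[key]["family"], kw[key].get("params", {}))
    for key in ("leak_slope_range", "i_release_range"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return PopulationParams(**kw)


def imaging_params_from_dict(d: dict) -> ImagingParams:
    return ImagingParams(**d)


def load_config(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
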