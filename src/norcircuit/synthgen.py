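"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per band, one shared oscillatory source (band-pass filtered white
noise) is mixed into the three regions with per-region gains and fixed
integer-sample delays (OB leads EC leads dHPC), on top of independent
1/f-like background noise per region. An impaired ("Abeta-like") group
is modeled by a multiplicative reduction of all coupling gains.
Tracking traces are a confined random walk with inserted dwell bouts at
the two objects; the fraction of dwell time at the novel object sets
the true discrimination index, DI_true = 2*p_novel - 1.

Every session carries a :class:`GroundTruth` with the analytic in-band
coherence per region pair, MSC = (SNR_x*SNR_y)/((1+SNR_x)(1+SNR_y))
with SNR the in-band PSD ratio of mixed source to noise, the injected
pairwise lags, the exact bout intervals and DI_true — the acceptance
surface every downstream stage is verified against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import CHANNELS, DEFAULT_BANDS, PAIRS, ArenaObject, Recording, TrackingTrace
from . import io as ncio

#: Group labels used by the default cohort: control then impaired.
GROUP_LABELS = ("saline", "abeta")


def _per_band(value, bands) -> dict:
    if isinstance(value, dict):
        return {b: float(value[b]) for b in bands}
    return {b: float(value) for b in bands}


def _per_region_band(value, bands) -> dict:
    if isinstance(value, dict) and set(value) >= set(CHANNELS):
        return {r: _per_band(value[r], bands) for r in CHANNELS}
    return {r: _per_band(value, bands) for r in CHANNELS}


@dataclass
class SynthParams:
    """Data-generating parameters for one group's sessions.

    The defaults encode the emulated study conditions: 1 kHz sampling,
    4-minute sessions, theta (4-12 Hz) and gamma (30-80 Hz) shared
    sources delayed 0/20/35 ms into OB/EC/dHPC, unit mixing gains over
    unit-variance 1/f background, and a novel-object preference of
    p_novel = 0.7876 over 5.65 s of total object exploration.
    """

    fs: float = 1000.0
    duration: float = 240.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    source_var: dict | float = field(
        default_factory=lambda: {"theta": 1.0, "gamma": 0.5})
    gains: dict | float = 1.0
    delays_ms: dict | float = field(
        default_factory=lambda: {"OB": 0.0, "EC": 20.0, "dHPC": 35.0})
    noise_var: dict | float = 1.0
    noise_exponent: float = 1.0
    noise_floor_hz: float = 1.0
    group_gain_factor: float = 1.0
    p_novel: float = 0.7876
    p_novel_sd: float = 0.05
    n_bouts: int = 4
    dwell_total_s: float = 5.65
    dwell_sd_frac: float = 0.2
    tracking_fs: float = 25.0
    arena: tuple = (75.0, 75.0)
    seed: int = 0

    def __post_init__(self):
        self.bands = {k: (float(v[0]), float(v[1])) for k, v in self.bands.items()}
        self._validate_bands()
        try:
            self.source_var = _per_band(self.source_var, self.bands)
        except KeyError as exc:
            raise ValueError(f"source_var missing band {exc}") from None
        self.gains = _per_region_band(self.gains, self.bands)
        self.delays_ms = _per_region_band(self.delays_ms, self.bands)
        self.noise_var = ({r: float(self.noise_var[r]) for r in CHANNELS}
                          if isinstance(self.noise_var, dict)
                          else {r: float(self.noise_var) for r in CHANNELS})
        self.validate()

    def _validate_bands(self) -> None:
        edges = sorted(self.bands.values())
        for (lo, hi) in edges:
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(f"band ({lo},{hi}) outside (0, fs/2)")
        for (a, b), (c, d) in zip(edges, edges[1:]):
            if b > c:
                raise ValueError("bands must be non-overlapping")
        if self.fs <= 2 * max(hi for _, hi in self.bands.values()):
            raise ValueError("fs must exceed twice the highest band edge")

    def validate(self) -> None:
        self._validate_bands()
        if not 0 <= self.group_gain_factor <= 1:
            raise ValueError("group_gain_factor must be in [0, 1]")
        if not 0 <= self.p_novel <= 1:
            raise ValueError("p_novel must be in [0, 1]")
        for r in CHANNELS:
            for b in self.bands:
                d = self.delays_ms[r][b]
                if d < 0 or d / 1000.0 >= self.duration:
                    raise ValueError("delays must be >= 0 and < duration")
        if self.n_bouts < 0:
            raise ValueError("n_bouts must be non-negative")

    def effective_gain(self, region: str, band: str) -> float:
        return self.gains[region][band] * self.group_gain_factor

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        d["arena"] = list(self.arena)
        return d


@dataclass
class GroundTruth:
    """Known truth for one generated session.

    coherence / lag_ms map "A-B" pair keys to per-band values; the lag
    sign follows the pipeline convention (positive = first-named region
    leads). DI_true = 2*p_novel - 1; bouts are exact sample-grid
    intervals (t of first and last sub-threshold tracking sample).
    """

    coherence: dict = field(default_factory=dict)
    lag_ms: dict = field(default_factory=dict)
    di_true: float = float("nan")
    bouts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coherence": self.coherence,
            "lag_ms": self.lag_ms,
            "di_true": self.di_true,
            "bouts": {k: [[float(a), float(b)] for a, b in v]
                      for k, v in self.bouts.items()},
        }


def pair_key(a: str, b: str) -> str:
    return f"{a}-{b}"


# ---------------------------------------------------------------------------
# analytic spectra

def _band_sos(band, fs, order=4):
    return sps.butter(order, list(band), btype="bandpass", fs=fs, output="sos")


def source_psd(band, fs, source_var, freqs) -> np.ndarray:
    """One-sided PSD of the band-limited source, normalized to its variance.

    The source is white noise passed forward-backward through a
    Butterworth band-pass, so its PSD shape is |H(f)|^4; the realized
    series is rescaled to exact variance, hence the normalization.
    """
    grid = np.linspace(0, fs / 2, 4096)
    sos = _band_sos(band, fs)
    _, h = sps.sosfreqz(sos, worN=grid, fs=fs)
    g4 = np.abs(h) ** 4
    total = np.trapezoid(g4, grid)
    _, h_out = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return source_var * np.abs(h_out) ** 4 / total


def noise_psd(fs, noise_var, freqs, exponent=1.0, floor_hz=1.0) -> np.ndarray:
    """One-sided PSD of the spectrally shaped background noise.

    Power density proportional to 1/f^exponent, floored below
    ``floor_hz`` (no infinite DC power), normalized to total variance.
    exponent=0 gives white noise.
    """
    grid = np.linspace(0, fs / 2, 4096)
    shape = np.maximum(grid, floor_hz) ** (-exponent)
    total = np.trapezoid(shape, grid)
    f = np.asarray(freqs, dtype=float)
    return noise_var * np.maximum(f, floor_hz) ** (-exponent) / total


def theoretical_msc(params: SynthParams, pair, band_name: str,
                    freqs=None) -> np.ndarray:
    """Analytic magnitude-squared coherence of a region pair over ``freqs``.

    Defaults to a fine grid across the named band. Within band b only
    source b contributes signal power; each region's SNR(f) is its
    mixed-source PSD over its noise PSD.
    """
    lo, hi = params.bands[band_name]
    if freqs is None:
        freqs = np.linspace(lo, hi, 257)
    s_src = source_psd(params.bands[band_name], params.fs,
                       params.source_var[band_name], freqs)
    msc = np.ones_like(s_src)
    for region in pair:
        g = params.effective_gain(region, band_name)
        s_noise = noise_psd(params.fs, params.noise_var[region], freqs,
                            params.noise_exponent, params.noise_floor_hz)
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = np.where(s_noise > 0, g * g * s_src / s_noise, np.inf)
            msc *= snr / (1.0 + snr)
    return np.where(np.isnan(msc), 1.0, msc)


def theoretical_band_msc(params: SynthParams, pair, band_name: str,
                         df: float = 1.0) -> float:
    """Band-average analytic coherence.

    Evaluated on the analysis frequency grid (bins ``df`` Hz apart,
    default 1 Hz — the resolution of 1 s Welch segments) so the value
    is directly comparable to a Welch band mean: the in-band MSC falls
    steeply at the band edges and a mismatch between grids would bias
    the comparison, not the estimator.
    """
    lo, hi = params.bands[band_name]
    freqs = np.arange(np.ceil(lo / df), np.floor(hi / df) + 1) * df
    return float(np.mean(theoretical_msc(params, pair, band_name, freqs=freqs)))


# ---------------------------------------------------------------------------
# signal generation

def _shaped_noise(n, fs, var, exponent, floor_hz, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    if exponent == 0:
        out = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        spec *= np.maximum(f, floor_hz) ** (-exponent / 2.0)
        out = np.fft.irfft(spec, n=n)
    sd = out.std()
    if sd == 0:
        return out
    return out * (np.sqrt(var) / sd)


def _band_source(n, fs, band, var, rng) -> np.ndarray:
    x = sps.sosfiltfilt(_band_sos(band, fs), rng.standard_normal(n))
    sd = x.std()
    return x * (np.sqrt(var) / sd)


def generate_recording(params: SynthParams, animal_id: str = "",
                       group_label: str = "", rng=None) -> tuple:
    """Generate one 3-channel session and its ground truth.

    Returns ``(Recording, GroundTruth)`` with the GroundTruth's
    coherence and lag fields filled (behavioral fields are filled by
    :func:`generate_tracking`). Delays are applied as integer sample
    shifts of each band's shared source (fractional-ms delays round to
    the nearest sample); the rounded values are what the ground truth
    reports.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    n = int(round(params.duration * params.fs))
    delays = {r: {b: int(round(params.delays_ms[r][b] * params.fs / 1000.0))
                  for b in params.bands} for r in CHANNELS}
    max_d = max(d for per in delays.values() for d in per.values())
    if max_d >= n:
        raise ValueError("delay exceeds signal length")
    data = np.zeros((len(CHANNELS), n))
    for b, band in params.bands.items():
        src = _band_source(n + max_d, params.fs, band, params.source_var[b], rng)
        for i, r in enumerate(CHANNELS):
            d = delays[r][b]
            data[i] += params.effective_gain(r, b) * src[max_d - d: max_d - d + n]
    for i, r in enumerate(CHANNELS):
        data[i] += _shaped_noise(n, params.fs, params.noise_var[r],
                                 params.noise_exponent, params.noise_floor_hz, rng)
    gt = GroundTruth()
    for a, b in PAIRS:
        key = pair_key(a, b)
        gt.coherence[key] = {bn: theoretical_band_msc(params, (a, b), bn)
                             for bn in params.bands}
        gt.lag_ms[key] = {bn: (delays[b][bn] - delays[a][bn]) * 1000.0 / params.fs
                          for bn in params.bands}
    rec = Recording(CHANNELS, data, fs=params.fs, animal_id=animal_id,
                    group_label=group_label)
    return rec, gt


# ---------------------------------------------------------------------------
# tracking generation

def default_objects(arena=(75.0, 75.0), radius: float = 5.0) -> list:
    """Two objects in opposite corners, centers 15 cm from the walls."""
    return [ArenaObject("novel", (15.0, 15.0), radius),
            ArenaObject("familiar", (arena[0] - 15.0, arena[1] - 15.0), radius)]


def _allocate_bouts(total_samples: int, n_bouts: int) -> list:
    """Split a dwell budget (in detected samples, i.e. sum of L-1) into bouts."""
    if total_samples <= 0 or n_bouts <= 0:
        return []
    n_bouts = min(n_bouts, total_samples)
    base, rem = divmod(total_samples, n_bouts)
    return [base + 1 + (1 if j < rem else 0) for j in range(n_bouts)]


def generate_tracking(params: SynthParams, arena=None, objects=None,
                      rng=None) -> tuple:
    """Generate a tracking trace with inserted exploration bouts.

    Outside bouts the body follows a clipped Ornstein-Uhlenbeck walk in
    the central region of the arena (nose always > 2.5 cm from both
    object surfaces); during a bout the nose sits within 2.5 cm of the
    object's center (distance 0 to its surface). Total dwell time is
    split p_novel : (1 - p_novel) between novel and familiar objects on
    the tracking sample grid, so detected bout durations reproduce the
    intended split exactly up to one sample. Returns
    ``(TrackingTrace, GroundTruth)`` with di_true and bouts filled.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    arena = tuple(arena or params.arena)
    objects = list(objects) if objects is not None else default_objects(arena)
    for obj in objects:
        if not (0 <= obj.center[0] <= arena[0] and 0 <= obj.center[1] <= arena[1]):
            raise ValueError(f"object {obj.label!r} outside arena")
    fs_t = params.tracking_fs
    n_t = int(round(params.duration * fs_t))
    dt = 1.0 / fs_t

    # dwell budget in "detected" samples (a bout of L samples spans (L-1)*dt)
    targets = {"novel": params.p_novel * params.dwell_total_s,
               "familiar": (1 - params.p_novel) * params.dwell_total_s}
    lengths = {lab: _allocate_bouts(int(round(tgt * fs_t)), params.n_bouts)
               for lab, tgt in targets.items()}
    order = [("novel", L) for L in lengths["novel"]] + \
            [("familiar", L) for L in lengths["familiar"]]
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]

    lead = int(round(3.0 * fs_t))          # keep the 2 s epoch pre-window clear
    tail = int(round(2.0 * fs_t))
    min_gap = int(round(2.5 * fs_t))
    total_bout = sum(L for _, L in order)
    k = len(order)
    slack = n_t - lead - tail - total_bout - min_gap * max(k - 1, 0)
    if slack < 0:
        raise ValueError("dwell time exceeds session duration")
    extra = rng.multinomial(slack, np.ones(k + 1) / (k + 1)) if k else []

    bouts = {"novel": [], "familiar": []}
    intervals = []
    pos = lead + (int(extra[0]) if k else 0)
    for j, (lab, L) in enumerate(order):
        i0, i1 = pos, pos + L - 1
        bouts[lab].append((i0 * dt, i1 * dt))
        intervals.append((lab, i0, i1))
        pos = i1 + 1 + min_gap + int(extra[j + 1])

    # body trajectory: OU walk confined to the central box [25, 50]^2 (cm),
    # scaled to the arena; guarantees nose > 2.5 cm from object surfaces
    lo = np.array([arena[0] / 3, arena[1] / 3])
    hi = np.array([2 * arena[0] / 3, 2 * arena[1] / 3])
    mu = (lo + hi) / 2
    body = np.empty((n_t, 2))
    body[0] = mu
    sigma, theta = 8.0, 0.5
    steps = rng.standard_normal((n_t - 1, 2))
    for i in range(1, n_t):
        drift = theta * (mu - body[i - 1]) * dt
        body[i] = np.clip(body[i - 1] + drift + sigma * np.sqrt(dt) * steps[i - 1],
                          lo, hi)
    heading = np.cumsum(rng.standard_normal(n_t) * 0.3)
    nose = body + 4.0 * np.column_stack([np.cos(heading), np.sin(heading)])

    for lab, i0, i1 in intervals:
        obj = next(o for o in objects if o.label == lab)
        c = np.array(obj.center)
        m = i1 - i0 + 1
        ang = rng.uniform(0, 2 * np.pi, m)
        rad = rng.uniform(0, 2.0, m)
        nose[i0:i1 + 1] = c + np.column_stack([rad * np.cos(ang),
                                               rad * np.sin(ang)])
        away = (np.array([arena[0] / 2, arena[1] / 2]) - c)
        away = away / np.linalg.norm(away)
        body[i0:i1 + 1] = c + away * (obj.radius + 3.0) + \
            rng.normal(0, 0.3, (m, 2))

    t = np.arange(n_t) * dt
    trace = TrackingTrace(t, body, nose, arena=arena, objects=objects)
    gt = GroundTruth(di_true=2 * params.p_novel - 1, bouts=bouts)
    return trace, gt


def generate_session(params: SynthParams, animal_id: str = "",
                     group_label: str = "", rng=None) -> tuple:
    """Generate one animal's recording + tracking + merged ground truth.

    Behavioral parameters get per-animal variability: the animal's
    novelty preference is drawn from N(p_novel, p_novel_sd) clipped to
    [0, 1] and its dwell budget from N(dwell_total_s,
    dwell_sd_frac * dwell_total_s) floored at 1 s, so cohort-level DI
    carries realistic between-animal spread. DI_true in the ground
    truth is the per-animal value.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    rec, gt = generate_recording(params, animal_id, group_label, rng)
    p_eff = float(np.clip(rng.normal(params.p_novel, params.p_novel_sd), 0, 1))
    dwell_eff = max(rng.normal(params.dwell_total_s,
                               params.dwell_sd_frac * params.dwell_total_s), 1.0)
    animal_params = dataclasses.replace(params, p_novel=p_eff,
                                        dwell_total_s=float(dwell_eff))
    trace, gt_b = generate_tracking(animal_params, rng=rng)
    gt.di_true = gt_b.di_true
    gt.bouts = gt_b.bouts
    return rec, trace, gt


def default_control_params(**overrides) -> SynthParams:
    """Control-group conditions (full coupling, strong novelty preference)."""
    return SynthParams(**overrides)


def default_impaired_params(**overrides) -> SynthParams:
    """Impaired-group conditions: halved coupling gains, weak novelty
    preference, reduced total exploration."""
    base = dict(group_gain_factor=0.5, p_novel=0.5494, dwell_total_s=3.60)
    base.update(overrides)
    return SynthParams(**base)


def generate_cohort_sessions(params_control: SynthParams,
                             params_impaired: SynthParams,
                             n_per_group: int = 6, seed: int = 0,
                             labels=GROUP_LABELS) -> list:
    """Generate an in-memory cohort: list of (animal_id, group, rec, trace, gt)."""
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    out = []
    for gi, (label, params) in enumerate(zip(labels,
                                             (params_control, params_impaired))):
        for j in range(n_per_group):
            animal = f"{label}{j + 1:02d}"
            rng = np.random.default_rng(children[gi * n_per_group + j])
            rec, trace, gt = generate_session(params, animal, label, rng)
            out.append((animal, label, rec, trace, gt))
    return out


def generate_cohort(params_control: SynthParams, params_impaired: SynthParams,
                    n_per_group: int, out_dir, seed: int = 0,
                    labels=GROUP_LABELS) -> dict:
    """Generate a cohort and write it to ``out_dir``; returns the manifest.

    Writes per animal ``<id>_lfp.tsv`` and ``<id>_tracking.tsv``, a
    ``groups.tsv`` table and ``manifest.json`` holding all parameters,
    per-animal ground truths and file checksums. Fully reproducible:
    the same seed yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = generate_cohort_sessions(params_control, params_impaired,
                                        n_per_group, seed, labels)
    rows, animals = [], {}
    for animal, label, rec, trace, gt in sessions:
        lfp = ncio.write_recording(rec, out_dir / f"{animal}_lfp.tsv")
        trk = ncio.write_tracking(trace, out_dir / f"{animal}_tracking.tsv")
        rows.append({"animal_id": animal, "group": label,
                     "lfp": lfp.name, "tracking": trk.name})
        animals[animal] = {
            "group": label, "ground_truth": gt.to_dict(),
            "files": {lfp.name: ncio.sha256(lfp), trk.name: ncio.sha256(trk)},
        }
    pd.DataFrame(rows).to_csv(out_dir / "groups.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "n_per_group": n_per_group,
        "labels": list(labels),
        "params": {labels[0]: params_control.to_dict(),
                   labels[1]: params_impaired.to_dict()},
        "objects": [{"label": o.label, "center": list(o.center),
                     "radius": o.radius}
                    for o in default_objects(params_control.arena)],
        "animals": animals,
        "notes": ("background noise follows an assumed 1/f spectral model "
                  "(exponent and low-frequency floor recorded in params); "
                  "delays are rounded to integer samples"),
    }
    ncio.write_json(manifest, out_dir / "manifest.json")
    return manifest
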