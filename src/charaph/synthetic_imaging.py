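"""Synthetic fluorescence time series emulating surface-pH confocal movies.

The generator produces what the study's imaging produced: time series of a
FITC-dextran-reported external pH field over a characean internode, at a
1.2 s frame interval, with stationary alkaline bands, and — under saline
stress — transient ~30 μm alkaline spots that appear randomly 10–18 min
after salt addition and rise/decay on 25/130 s or 50/190 s time scales.
FITC is used non-ratiometrically: its response is linear between pH 5 and
7.5 and saturates above, so spot peak pH (default 9, an assumption) is not
directly readable from intensity.  Photon (Poisson) and read (Gaussian)
noise are applied before quantization.

Scenario switches mirror the experimental conditions: ``control_afw``
(bands, no transient spots), ``sorbitol`` (osmotic control — bands, no
spots), ``saline`` (bands lost, spots after an onset delay drawn uniformly
from 10–18 min), and ``saline_zncl2`` (Zn²⁺ block — spot rate decays to
zero within minutes).

Ground truth is emitted alongside every movie.  Because of the FITC
saturation, event visibility is defined on the noiseless disk-mean
intensity signal of each event (mean over a disk of the event radius,
background subtracted): an event is visible while that signal exceeds 10%
of its own peak.  The detection pipeline measures the same observable, so
generator and detector share one lifetime convention.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


@dataclass(frozen=True)
class FitcResponse:
    """Non-ratiometric FITC calibration: linear on [5, 7.5], flat above.

    The response is also flat below pH 5 (outside the calibrated range);
    all pH values of interest here are >= 5.
    """

    linear_low: float = 5.0
    linear_high: float = 7.5

    def fraction(self, ph: np.ndarray | float) -> np.ndarray | float:
        """Fraction of full-scale response in [0, 1]."""
        return (np.clip(ph, self.linear_low, self.linear_high) - self.linear_low) / (
            self.linear_high - self.linear_low
        )

    def intensity(
        self, ph: np.ndarray | float, gain: float, offset: float
    ) -> np.ndarray | float:
        """Mean intensity for a pH map: offset + gain·(clipped pH − 5)."""
        return offset + gain * (
            np.clip(ph, self.linear_low, self.linear_high) - self.linear_low
        )


FITC = FitcResponse()


@dataclass(frozen=True)
class NoiseModel:
    photon: bool = True
    read_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition parameters of one synthetic movie.

    ``gain`` is intensity units per pH unit inside the linear range,
    ``offset`` the dark level.  The seed fixes the movie bit-exactly.
    """

    frame_count: int
    frame_interval: float = 1.2
    image_size: tuple[int, int] = (256, 256)
    pixel_size: float = 1.5
    background_ph: float = 5.6
    gain: float = 50.0
    offset: float = 200.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    bit_depth: Literal[16, 32] = 16

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0 s")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0 μm")
        if self.bit_depth not in (16, 32):
            raise ValueError("bit_depth must be 16 or 32")

    @property
    def duration(self) -> float:
        return self.frame_count * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frame_count) * self.frame_interval


def config_for_snr(
    snr: float,
    frame_count: int,
    offset: float = 200.0,
    read_sigma: float = 3.0,
    photon: bool = True,
    **kwargs,
) -> ImagingConfig:
    """Build a config whose saturated-spot amplitude is ``snr`` times the
    total per-pixel noise standard deviation at the spot center.

    Amplitude A = gain·(7.5 − background pH); noise variance at the center
    is (offset + gain·2.5) photon variance plus read variance.  Solving
    A = snr·σ for the gain gives a quadratic with one positive root.
    """
    background_ph = kwargs.pop("background_ph", 5.6)
    span = FITC.linear_high - max(background_ph, FITC.linear_low)
    full = FITC.linear_high - FITC.linear_low
    if photon:
        a = span * span
        b = -(snr**2) * full
        c = -(snr**2) * (offset + read_sigma**2)
        gain = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    else:
        if read_sigma <= 0:
            raise ValueError("need read noise when photon noise is off")
        gain = snr * read_sigma / span
    return ImagingConfig(
        frame_count=frame_count,
        background_ph=background_ph,
        gain=gain,
        offset=offset,
        noise=NoiseModel(photon=photon, read_sigma=read_sigma),
        **kwargs,
    )


@dataclass(frozen=True)
class GroundTruthEvent:
    """One generated alkaline-spot event (times in seconds, center in px)."""

    event_id: int
    center: tuple[float, float]      # (row, col), 0-based pixels
    radius_um: float                 # visible radius; Gaussian sigma = radius/2
    onset_time: float
    rise_time: float
    decay_time: float
    peak_ph: float = 9.0
    persistent: bool = False
    envelope: Literal["linear", "exp"] = "linear"

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")
        if not self.persistent and not (self.rise_time > 0 and self.decay_time > 0):
            raise ValueError("transient events need positive rise and decay times")

    def envelope_at(self, t: float) -> float:
        """Temporal envelope in [0, 1]: linear 0→1 over rise_time, then
        (for transients) linear 1→0 over decay_time, or an exponential
        decay reaching 10% at onset + rise + decay."""
        dt = t - self.onset_time
        if dt < 0:
            return 0.0
        if dt <= self.rise_time:
            return dt / self.rise_time if self.rise_time > 0 else 1.0
        if self.persistent:
            return 1.0
        fall = dt - self.rise_time
        if self.envelope == "exp":
            tau = self.decay_time / math.log(10.0)
            return math.exp(-fall / tau)
        return max(0.0, 1.0 - fall / self.decay_time)


@dataclass(frozen=True)
class BandSpec:
    """A stationary alkaline band: a stripe of elevated pH across the field."""

    center_col: int
    width: int
    ph: float


@dataclass(frozen=True)
class Scenario:
    """Experimental condition switches for the generator."""

    label: Literal["control_afw", "sorbitol", "saline", "saline_zncl2"]
    spot_rate: float = 2.0                      # events/min over the field
    onset_delay_range: tuple[float, float] = (10.0, 18.0)  # min
    bands: tuple[BandSpec, ...] = ()
    zn_suppression: bool = False
    zn_decay_s: float = 120.0
    kinetics: tuple[tuple[float, float], ...] = ((25.0, 130.0), (50.0, 190.0))
    peak_ph: float = 9.0
    envelope: Literal["linear", "exp"] = "linear"


DEFAULT_BANDS = (BandSpec(center_col=190, width=40, ph=7.2),)


def scenario(label: str, **overrides) -> Scenario:
    """Named scenario presets matching the experimental conditions."""
    presets = {
        "control_afw": dict(spot_rate=0.0, bands=DEFAULT_BANDS),
        "sorbitol": dict(spot_rate=0.0, bands=DEFAULT_BANDS),
        "saline": dict(bands=()),
        "saline_zncl2": dict(bands=(), zn_suppression=True),
    }
    if label not in presets:
        raise ValueError(f"unknown scenario {label!r}; expected {sorted(presets)}")
    params = {**presets[label], **overrides}
    return Scenario(label=label, **params)


def generate_events(
    scen: Scenario, config: ImagingConfig, rng: np.random.Generator
) -> list[GroundTruthEvent]:
    """Draw ground-truth events for a scenario.

    Control and sorbitol scenarios produce none.  Saline events form a
    Poisson process at ``spot_rate`` starting after the onset delay (drawn
    uniformly from ``onset_delay_range`` minutes); with Zn²⁺ suppression
    the rate instead decays exponentially from time zero.  Events are
    placed away from image borders, mutually separated by three radii, and
    only started if their full envelope completes before the movie ends.
    """
    if scen.label in ("control_afw", "sorbitol") or scen.spot_rate <= 0:
        return []
    t_total = config.duration
    radius_um = 15.0
    radius_px = radius_um / config.pixel_size
    margin = 2.5 * radius_px
    min_sep = 3.0 * radius_px
    rate_s = scen.spot_rate / 60.0

    if scen.zn_suppression:
        start = 0.0
    else:
        start = rng.uniform(*scen.onset_delay_range) * 60.0

    # candidate onset times by Poisson thinning of the maximal rate
    onsets: list[float] = []
    t = start
    while True:
        t += rng.exponential(1.0 / rate_s)
        if t >= t_total:
            break
        if scen.zn_suppression:
            if rng.uniform() > math.exp(-t / scen.zn_decay_s):
                continue
        onsets.append(t)

    events: list[GroundTruthEvent] = []
    centers: list[tuple[float, float]] = []
    rows, cols = config.image_size
    for onset in onsets:
        rise, decay = scen.kinetics[rng.integers(len(scen.kinetics))]
        if onset + rise + decay > t_total:
            continue  # envelope would be truncated by the end of the movie
        placed = None
        for _ in range(200):
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            if all(math.hypot(r - r0, c - c0) >= min_sep for r0, c0 in centers):
                placed = (r, c)
                break
        if placed is None:
            continue  # field saturated with spots
        centers.append(placed)
        events.append(
            GroundTruthEvent(
                event_id=len(events),
                center=placed,
                radius_um=radius_um,
                onset_time=onset,
                rise_time=rise,
                decay_time=decay,
                peak_ph=scen.peak_ph,
                envelope=scen.envelope,
            )
        )
    return events


def static_ph_field(scen: Scenario, config: ImagingConfig) -> np.ndarray:
    """Background pH plus stationary bands (time-independent part)."""
    rows, cols = config.image_size
    ph = np.full((rows, cols), config.background_ph, dtype=float)
    for band in scen.bands:
        lo = max(0, band.center_col - band.width // 2)
        hi = min(cols, band.center_col + (band.width + 1) // 2)
        ph[:, lo:hi] = np.maximum(ph[:, lo:hi], band.ph)
    return ph


def ph_field(
    scen: Scenario,
    config: ImagingConfig,
    t: float,
    events: Sequence[GroundTruthEvent] = (),
    static: np.ndarray | None = None,
) -> np.ndarray:
    """The full 2D pH map at time t: background + bands + event bumps.

    Each active event adds a Gaussian spatial bump (sigma = radius/2 in
    pixels) scaled by its temporal envelope; the bump peaks at
    ``peak_ph − background`` above background at the event center.
    """
    base = static_ph_field(scen, config) if static is None else static
    ph = base.copy()
    for ev in events:
        env = ev.envelope_at(t)
        if env <= 0.0:
            continue
        amp = (ev.peak_ph - config.background_ph) * env
        sigma = ev.radius_um / 2.0 / config.pixel_size
        r0, c0 = ev.center
        half = int(math.ceil(3.0 * sigma))
        rlo = max(0, int(r0) - half)
        rhi = min(config.image_size[0], int(r0) + half + 1)
        clo = max(0, int(c0) - half)
        chi = min(config.image_size[1], int(c0) + half + 1)
        rr = np.arange(rlo, rhi)[:, None] - r0
        cc = np.arange(clo, chi)[None, :] - c0
        ph[rlo:rhi, clo:chi] += amp * np.exp(
            -(rr**2 + cc**2) / (2.0 * sigma**2)
        )
    return ph


@dataclass
class MovieResult:
    """A rendered movie with its ground truth."""

    stack: np.ndarray                 # (frames, rows, cols)
    events: list[GroundTruthEvent]
    events_table: pd.DataFrame        # one row per event
    visibility_table: pd.DataFrame    # one row per (event, visible frame)
    clipped_pixels: int


def _disk_mask(
    shape: tuple[int, int], center: tuple[float, float], radius_px: float
) -> tuple[slice, slice, np.ndarray]:
    r0, c0 = center
    half = int(math.ceil(radius_px))
    rlo = max(0, int(r0) - half)
    rhi = min(shape[0], int(r0) + half + 1)
    clo = max(0, int(c0) - half)
    chi = min(shape[1], int(c0) + half + 1)
    rr = np.arange(rlo, rhi)[:, None] - r0
    cc = np.arange(clo, chi)[None, :] - c0
    mask = rr**2 + cc**2 <= radius_px**2
    return slice(rlo, rhi), slice(clo, chi), mask


def render_movie(
    scen: Scenario,
    config: ImagingConfig,
    events: list[GroundTruthEvent] | None = None,
) -> MovieResult:
    """Render a movie frame by frame and tabulate its ground truth.

    Intensity is the FITC response of the pH field scaled by gain/offset;
    photon (Poisson) noise is applied first, then Gaussian read noise, then
    clipping and quantization to the configured bit depth (16-bit movies
    are unsigned integers; 32-bit movies are float32 and not quantized).
    The same seed reproduces the movie bit-exactly.  ``events`` overrides
    the scenario's random event draw (for controlled experiments).
    """
    rng = np.random.default_rng(config.seed)
    if events is None:
        events = generate_events(scen, config, rng)
    static = static_ph_field(scen, config)
    static_intensity = FITC.intensity(static, config.gain, config.offset)

    n = config.frame_count
    rows, cols = config.image_size
    dtype = np.uint16 if config.bit_depth == 16 else np.float32
    stack = np.empty((n, rows, cols), dtype=dtype)
    signals = np.zeros((len(events), n))
    masks = [
        _disk_mask((rows, cols), ev.center, ev.radius_um / config.pixel_size)
        for ev in events
    ]
    clipped = 0
    max_value = 2**16 - 1

    for k in range(n):
        t = k * config.frame_interval
        ph = ph_field(scen, config, t, events, static=static)
        clean = FITC.intensity(ph, config.gain, config.offset)
        for j, (rsl, csl, mask) in enumerate(masks):
            signals[j, k] = np.mean(
                clean[rsl, csl][mask] - static_intensity[rsl, csl][mask]
            )
        frame = clean
        if config.noise.photon:
            frame = rng.poisson(frame).astype(float)
        if config.noise.read_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise.read_sigma, frame.shape)
        if config.bit_depth == 16:
            clipped += int(np.count_nonzero((frame < 0) | (frame > max_value)))
            stack[k] = np.clip(np.rint(frame), 0, max_value).astype(np.uint16)
        else:
            stack[k] = frame.astype(np.float32)

    event_rows = []
    vis_rows = []
    for j, ev in enumerate(events):
        sig = signals[j]
        amp = sig.max()
        visible = sig >= 0.1 * amp if amp > 0 else np.zeros(n, bool)
        frames_visible = np.nonzero(visible)[0]
        if frames_visible.size == 0:
            continue
        onset_f = int(frames_visible[0])
        end_f = int(frames_visible[-1])
        peak_f = int(np.argmax(sig))
        # FITC saturation flattens the top of the signal, so rise/decay
        # are measured to the edges of the 95%-of-peak plateau (the same
        # convention the detection pipeline applies)
        high = np.nonzero(sig >= 0.95 * amp)[0]
        rise_end_f = int(high[0])
        fall_start_f = int(high[-1])
        event_rows.append(
            {
                "event_id": ev.event_id,
                "row": ev.center[0],
                "col": ev.center[1],
                "radius_um": ev.radius_um,
                "onset_s": ev.onset_time,
                "rise_s": ev.rise_time,
                "decay_s": ev.decay_time,
                "peak_ph": ev.peak_ph,
                "persistent": ev.persistent,
                "visible_onset_frame": onset_f,
                "peak_frame": peak_f,
                "visible_end_frame": end_f,
                "lifetime_s": (end_f - onset_f) * config.frame_interval,
                "rise_obs_s": (rise_end_f - onset_f) * config.frame_interval,
                "decay_obs_s": (end_f - fall_start_f) * config.frame_interval,
            }
        )
        for f in frames_visible:
            vis_rows.append({"event_id": ev.event_id, "frame": int(f)})

    events_table = pd.DataFrame(
        event_rows,
        columns=[
            "event_id", "row", "col", "radius_um", "onset_s", "rise_s",
            "decay_s", "peak_ph", "persistent", "visible_onset_frame",
            "peak_frame", "visible_end_frame", "lifetime_s", "rise_obs_s",
            "decay_obs_s",
        ],
    )
    visibility_table = pd.DataFrame(vis_rows, columns=["event_id", "frame"])
    return MovieResult(
        stack=stack,
        events=events,
        events_table=events_table,
        visibility_table=visibility_table,
        clipped_pixels=clipped,
    )


def write_movie(
    out_dir: str | Path,
    result: MovieResult,
    config: ImagingConfig,
    scen: Scenario,
) -> dict[str, str]:
    """Write TIFF stack, ground-truth CSVs, and a config echo; return the
    written paths keyed by artifact name, with SHA-256 checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiff_path = out / "movie.tif"
    tifffile.imwrite(tiff_path, result.stack, photometric="minisblack")
    events_path = out / "ground_truth_events.csv"
    result.events_table.to_csv(events_path, index=False)
    vis_path = out / "ground_truth_visibility.csv"
    result.visibility_table.to_csv(vis_path, index=False)
    config_path = out / "config.yaml"
    echo = {
        "scenario": {
            "label": scen.label,
            "spot_rate_per_min": scen.spot_rate,
            "onset_delay_range_min": list(scen.onset_delay_range),
            "zn_suppression": scen.zn_suppression,
            "peak_ph": scen.peak_ph,
        },
        "imaging": {
            "frame_count": config.frame_count,
            "frame_interval_s": config.frame_interval,
            "image_size": list(config.image_size),
            "pixel_size_um": config.pixel_size,
            "background_ph": config.background_ph,
            "gain": config.gain,
            "offset": config.offset,
            "read_sigma": config.noise.read_sigma,
            "photon_noise": config.noise.photon,
            "seed": config.seed,
            "bit_depth": config.bit_depth,
        },
    }
    config_path.write_text(yaml.safe_dump(echo, sort_keys=False))
    artifacts = {}
    for name, path in (
        ("movie", tiff_path),
        ("events", events_path),
        ("visibility", vis_path),
        ("config", config_path),
    ):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        artifacts[name] = {"path": str(path), "sha256": digest}
    return artifacts
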