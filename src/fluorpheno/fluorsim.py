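"""Synthetic fluorescence data generator.

Renders rosette scenes and forward-simulates per-pixel quenching kinetics
and UV-excited multicolor band emission under control/drought presets with
known per-pixel ground truth, so the downstream extraction pipeline can be
validated against injected physiology.

Forward model (per leaf pixel)
------------------------------
Dark phase:       F = Fo under measuring light, F = Fm during a flash.
Actinic phase:    NPQ(t)   = npq_ss * (1 - exp(-k_ind * (t - t_on)))
                  Fm'(t)   = Fm / (1 + NPQ(t))
                  Phi(t)   = phi_ss + (phi0 - phi_ss) * exp(-k_p * (t - t_on))
                  Ft(t)    = Fm'(t) * (1 - Phi(t))
                  During a saturating flash Phi -> 0, so F -> Fm'(t).
Dark relaxation:  NPQ decays as exp(-k_rel * (t - t_off)) from its value at
                  light-off; Phi relaxes back to the dark-adapted yield, so
                  Ft decays toward Fo' and ultimately Fo.

The Kautsky peak Fp arises because Ft jumps from Fo to ~Fm*(1 - phi0) at
light onset and then declines as photochemistry and NPQ engage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse

from .config import default_config
from .protocol import ProtocolDefinition, default_quenching_protocol

__all__ = [
    "RosetteSpec",
    "PhysiologyTruth",
    "DroughtPreset",
    "NoiseModel",
    "FrameStack",
    "CohortSample",
    "BANDS",
    "generate_rosette",
    "make_truth",
    "frame_schedule",
    "simulate_stack",
    "simulate_multicolor",
    "simulate_cohort",
    "get_preset",
    "control_preset",
    "cohort_manifest",
]

#: UV-excited emission bands: blue 440 nm, green 520 nm, red 680 nm,
#: far-red 740 nm.
BANDS: tuple[str, ...] = ("BF", "GF", "RF", "IrF")

_MULT_KEYS = ("fvfm_true", "npq_ss", "phi_ss", "BF", "GF", "RF", "IrF")


@dataclass
class RosetteSpec:
    """Geometry of a synthetic rosette scene."""

    image_shape: tuple[int, int] = (48, 48)
    n_leaves: int = 8
    leaf_length_px: tuple[float, float] = (7.0, 10.0)
    leaf_width_px: tuple[float, float] = (2.5, 4.0)
    center: tuple[float, float] | None = None
    seed: int = 0


@dataclass
class DroughtPreset:
    """Severity preset: multiplicative physiology shifts plus a spatial
    gradient concentrating the effect at leaf tips and edges."""

    name: str
    day: int
    multipliers: dict[str, float]
    edge_gradient: float = 0.0
    between_plant_sd: float = 0.0


@dataclass
class NoiseModel:
    """Gaussian read noise plus signal-proportional variance."""

    read_sd: float = 2.0
    shot_scale: float = 0.5
    seed: int = 0

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseModel":
        return cls(read_sd=0.0, shot_scale=0.0, seed=seed)


@dataclass
class PhysiologyTruth:
    """Per-pixel ground-truth physiology driving the forward model."""

    mask: np.ndarray
    fm_amp: np.ndarray          # dark-adapted maximal fluorescence, counts
    fvfm_true: np.ndarray       # Fo = fm_amp * (1 - fvfm_true)
    npq_ss: np.ndarray          # steady-state NPQ
    phi_ss: np.ndarray          # steady-state PSII operating efficiency
    band_em: dict[str, np.ndarray]
    phi0: float = 0.05          # PSII yield at light onset
    k_ind: float = 0.25         # NPQ induction rate, 1/s
    k_rel: float = 0.08         # NPQ dark-relaxation rate, 1/s
    k_p: float = 0.35           # photochemical induction rate, 1/s

    def mean(self, key: str) -> float:
        """Mask-mean of a truth map (band names index ``band_em``)."""
        arr = self.band_em[key] if key in self.band_em else getattr(self, key)
        return float(np.mean(arr[self.mask]))


@dataclass
class FrameStack:
    """Timestamped 2-D count images with per-frame light-state labels."""

    frames: np.ndarray          # (n, rows, cols)
    times_s: np.ndarray         # (n,)
    light_state: np.ndarray     # (n,) of {dark, actinic, saturating, uv}
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.frames) == len(self.times_s) == len(self.light_state)):
            raise ValueError("frames, times_s and light_state must have equal length")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class CohortSample:
    plant_id: str
    label: int                  # 1 = control, 2 = drought-stressed
    preset_name: str
    seed: int
    truth: PhysiologyTruth
    stack: FrameStack
    multicolor: FrameStack


# ---------------------------------------------------------------------------
# presets

def control_preset(between_plant_sd: float | None = None, config: dict | None = None) -> DroughtPreset:
    p = get_preset("control", config)
    if between_plant_sd is not None:
        p.between_plant_sd = between_plant_sd
    return p


def get_preset(name: str, config: dict | None = None) -> DroughtPreset:
    """Look up a severity preset (``control``, ``day1``..``day8``, or the
    aliases ``moderate``/``severe``) from the config table."""
    cfg = config or default_config()
    key = cfg.get("preset_aliases", {}).get(name, name)
    try:
        entry = cfg["presets"][key]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(cfg['presets'])}")
    return DroughtPreset(
        name=key,
        day=int(entry.get("day", 0)),
        multipliers=dict(entry["multipliers"]),
        edge_gradient=float(entry.get("edge_gradient", 0.0)),
        between_plant_sd=float(entry.get("between_plant_sd", 0.0)),
    )


# ---------------------------------------------------------------------------
# scene generation

def generate_rosette(spec: RosetteSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize a rosette of elliptical leaves radiating from the center.

    Returns ``(mask, leaf_id_map, edge_distance_map)``: a boolean canopy
    mask, integer leaf labels 1..n_leaves (first leaf wins on overlap), and
    the Euclidean distance to the nearest background pixel (0 at the leaf
    boundary, maximal along the midrib).
    """
    rows, cols = spec.image_shape
    mask = np.zeros((rows, cols), dtype=bool)
    leaf_id = np.zeros((rows, cols), dtype=np.int32)
    if spec.n_leaves == 0:
        return mask, leaf_id, np.zeros((rows, cols))
    rng = np.random.default_rng(spec.seed)
    cr, cc = spec.center if spec.center is not None else ((rows - 1) / 2.0, (cols - 1) / 2.0)
    lo_l, hi_l = spec.leaf_length_px
    lo_w, hi_w = spec.leaf_width_px
    if lo_l <= 0 or lo_w <= 0:
        raise ValueError("leaf dimensions must be positive")
    angles = np.linspace(0.0, 2.0 * np.pi, spec.n_leaves, endpoint=False)
    angles = angles + rng.uniform(-0.2, 0.2, spec.n_leaves)
    for i, theta in enumerate(angles, start=1):
        a = rng.uniform(lo_l, hi_l)       # semi-major axis
        b = rng.uniform(lo_w, hi_w)       # semi-minor axis
        # leaf grows outward: ellipse centered one semi-major axis out
        er = cr + a * np.sin(theta)
        ec = cc + a * np.cos(theta)
        # the ellipse extends at most one semi-major axis from its center
        if er - a < -0.5 or er + a > rows - 0.5 or ec - a < -0.5 or ec + a > cols - 0.5:
            raise ValueError(
                f"leaf {i} (a={a:.1f}) does not fit inside image {spec.image_shape}"
            )
        rr, cc_px = _draw_ellipse(er, ec, b, a, shape=(rows, cols), rotation=-theta)
        new = np.zeros_like(mask)
        new[rr, cc_px] = True
        leaf_id[new & (leaf_id == 0)] = i
        mask |= new
    edge = ndimage.distance_transform_edt(mask)
    return mask, leaf_id, edge


def make_truth(
    mask: np.ndarray,
    preset: DroughtPreset,
    base_config: dict | None = None,
    seed: int = 0,
) -> PhysiologyTruth:
    """Build per-pixel ground truth for one plant under a severity preset.

    Each affected map is ``baseline * multiplier * (1 + edge_gradient *
    (1 - d/d_max))`` where ``d`` is the distance to the leaf edge, so the
    stress effect is strongest at leaf tips and edges. A per-plant random
    effect (one multiplicative factor per parameter, CV =
    ``between_plant_sd``) models between-pot variation.
    """
    cfg = base_config or default_config()["simulator"]["baseline"]
    rng = np.random.default_rng(seed)
    edge = ndimage.distance_transform_edt(mask)
    d_max = edge.max()
    grad = 1.0 + preset.edge_gradient * (1.0 - edge / d_max) if d_max > 0 else np.ones_like(edge)

    plant_factor = {
        k: max(0.05, 1.0 + rng.normal(0.0, preset.between_plant_sd))
        if preset.between_plant_sd > 0
        else 1.0
        for k in _MULT_KEYS
    }

    def _map(base: float, key: str, clip_hi: float | None = None) -> np.ndarray:
        m = np.zeros(mask.shape)
        vals = base * preset.multipliers.get(key, 1.0) * plant_factor[key] * grad[mask]
        if clip_hi is not None:
            vals = np.clip(vals, 0.0, clip_hi)
        m[mask] = np.maximum(vals, 0.0)
        return m

    phi0 = float(cfg.get("phi0", 0.05))
    phi_ss = _map(cfg["phi_ss"], "phi_ss", clip_hi=0.98)
    phi_ss[mask] = np.maximum(phi_ss[mask], phi0 + 0.01)
    return PhysiologyTruth(
        mask=mask.copy(),
        fm_amp=_flat(mask, cfg["fm_amp"]),
        fvfm_true=_map(cfg["fvfm_true"], "fvfm_true", clip_hi=0.98),
        npq_ss=_map(cfg["npq_ss"], "npq_ss"),
        phi_ss=phi_ss,
        band_em={b: _map(cfg["band_em"][b], b) for b in BANDS},
        phi0=phi0,
        k_ind=float(cfg.get("k_ind", 0.25)),
        k_rel=float(cfg.get("k_rel", 0.08)),
        k_p=float(cfg.get("k_p", 0.35)),
    )


def _flat(mask: np.ndarray, value: float) -> np.ndarray:
    m = np.zeros(mask.shape)
    m[mask] = value
    return m


# ---------------------------------------------------------------------------
# frame schedule and kinetic rendering

def frame_schedule(p: ProtocolDefinition) -> tuple[np.ndarray, np.ndarray]:
    """Frame times and light states implied by a protocol.

    Base sampling at ``frame_rate_hz`` over the whole timeline, densified
    at ``flash_frame_rate_hz`` inside every flash window, at 10 Hz in the
    1 s window preceding each saturating flash (the Ft pre-flash window),
    and at 20 Hz for 3 s after actinic onset so the Kautsky peak Fp is
    resolved.
    """
    end = p.end_s + 2.0
    times = [np.arange(0.0, end, 1.0 / p.frame_rate_hz)]
    for ev in p.flashes:
        times.append(np.arange(ev.time_s, ev.end_s, 1.0 / p.flash_frame_rate_hz))
        if ev.kind == "saturating":
            times.append(np.arange(ev.time_s - 1.0, ev.time_s - 1e-9, 0.1))
    times.append(np.arange(p.actinic_on_s, p.actinic_on_s + 3.0, 0.05))
    if p.fp_time_s is not None:
        times.append(np.array([p.fp_time_s]))
    tt = np.unique(np.round(np.concatenate(times), 5))
    tt = tt[tt >= 0]

    state = np.full(tt.shape, "dark", dtype=object)
    state[(tt > p.actinic_on_s) & (tt <= p.actinic_off_s)] = "actinic"
    for ev in p.flashes:
        if ev.kind == "saturating":
            state[(tt >= ev.time_s) & (tt < ev.end_s)] = "saturating"
    return tt, state.astype(str)


def _render(truth: PhysiologyTruth, p: ProtocolDefinition, times: np.ndarray, state: np.ndarray) -> np.ndarray:
    """Evaluate the pixel model at each frame time. Returns (n, r, c)."""
    mask = truth.mask
    fm = truth.fm_amp[mask]
    fo = fm * (1.0 - truth.fvfm_true[mask])
    npq_pix = truth.npq_ss[mask]
    phi_pix = truth.phi_ss[mask]
    fvfm_pix = truth.fvfm_true[mask]
    t_on = p.actinic_on_s
    # a flash fired at actinic-off (the Lss flash) keeps the leaf in the
    # light state until the flash ends; relaxation starts after it
    light_ends = [ev.end_s for ev in p.saturating_flashes("light")]
    t_off = max([p.actinic_off_s] + light_ends)

    frac = np.zeros_like(times)
    in_light = times > t_on
    frac[in_light] = 1.0 - np.exp(-truth.k_ind * (times[in_light] - t_on))
    after = times > t_off
    frac_off = 1.0 - np.exp(-truth.k_ind * (t_off - t_on))
    frac[after] = frac_off * np.exp(-truth.k_rel * (times[after] - t_off))

    npq_t = frac[:, None] * npq_pix[None, :]          # (n, npix)
    fmp = fm[None, :] / (1.0 + npq_t)

    phi = np.empty_like(npq_t)
    dark0 = times <= t_on
    phi[dark0] = fvfm_pix[None, :]
    lit = in_light & ~after
    decay = np.exp(-truth.k_p * (times[lit] - t_on))[:, None]
    phi[lit] = phi_pix[None, :] + (truth.phi0 - phi_pix[None, :]) * decay
    phi_at_off = phi_pix + (truth.phi0 - phi_pix) * np.exp(-truth.k_p * (t_off - t_on))
    relax = np.exp(-truth.k_p * (times[after] - t_off))[:, None]
    phi[after] = fvfm_pix[None, :] + (phi_at_off[None, :] - fvfm_pix[None, :]) * relax

    sat = state == "saturating"
    f = np.where(sat[:, None], fmp, fmp * (1.0 - phi))
    f[dark0 & ~sat] = fo[None, :]  # dark-adapted, measuring light only

    frames = np.zeros((len(times),) + mask.shape)
    frames[:, mask] = f
    return frames


def _apply_noise(frames: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.read_sd == 0 and noise.shot_scale == 0:
        return frames
    out = frames + rng.normal(0.0, noise.read_sd, frames.shape)
    if noise.shot_scale > 0:
        out = out + rng.standard_normal(frames.shape) * np.sqrt(
            noise.shot_scale * np.clip(frames, 0.0, None)
        )
    return np.clip(out, 0.0, None)


def simulate_stack(
    truth: PhysiologyTruth,
    p: ProtocolDefinition | None = None,
    noise: NoiseModel | None = None,
) -> FrameStack:
    """Forward-simulate a quenching-kinetics frame stack for one plant."""
    if not truth.mask.any():
        raise ValueError("empty plant mask")
    p = p or default_quenching_protocol()
    noise = noise or NoiseModel.none()
    times, state = frame_schedule(p)
    frames = _render(truth, p, times, state)
    rng = np.random.default_rng(noise.seed)
    frames = _apply_noise(frames, noise, rng)
    return FrameStack(
        frames=frames,
        times_s=times,
        light_state=state,
        meta={"protocol": "default_quenching", "seed": noise.seed},
    )


def simulate_multicolor(
    truth: PhysiologyTruth,
    noise: NoiseModel | None = None,
    n_exposures: int = 5,
    exposure_s: float = 4.0,
) -> FrameStack:
    """Simulate the UV-excited multicolor acquisition: ``n_exposures``
    frames per band (BF, GF, RF, IrF), each with mean equal to the band
    emission map; 4 x 5 = 20 frames by default."""
    if not truth.mask.any():
        raise ValueError("empty plant mask")
    noise = noise or NoiseModel.none()
    rng = np.random.default_rng(noise.seed + 1)
    frames, bands = [], []
    for band in BANDS:
        base = truth.band_em[band]
        for _ in range(n_exposures):
            frames.append(_apply_noise(base[None], noise, rng)[0])
            bands.append(band)
    times = np.arange(len(frames)) * exposure_s
    return FrameStack(
        frames=np.stack(frames),
        times_s=times,
        light_state=np.full(len(frames), "uv"),
        meta={"bands": bands, "seed": noise.seed},
    )


# ---------------------------------------------------------------------------
# cohorts

def simulate_cohort(
    n_control: int,
    n_drought: int,
    preset: DroughtPreset | str,
    protocol: ProtocolDefinition | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    rosette: RosetteSpec | None = None,
    base_config: dict | None = None,
    config: dict | None = None,
) -> list[CohortSample]:
    """Simulate a labelled cohort: ``n_control`` plants under the control
    preset (label 1) and ``n_drought`` under ``preset`` (label 2). Each
    plant gets its own rosette geometry, physiology draw and noise seed,
    all derived deterministically from ``seed``."""
    if n_control < 0 or n_drought < 0:
        raise ValueError("cohort sizes must be >= 0")
    cfg = config or default_config()
    if isinstance(preset, str):
        preset = get_preset(preset, cfg)
    protocol = protocol or default_quenching_protocol()
    noise = noise or NoiseModel(**cfg["simulator"]["noise"])
    rosette = rosette or RosetteSpec(
        image_shape=tuple(cfg["simulator"]["rosette"]["image_shape"]),
        n_leaves=int(cfg["simulator"]["rosette"]["n_leaves"]),
        leaf_length_px=tuple(cfg["simulator"]["rosette"]["leaf_length_px"]),
        leaf_width_px=tuple(cfg["simulator"]["rosette"]["leaf_width_px"]),
    )
    ctrl = control_preset(between_plant_sd=preset.between_plant_sd, config=cfg)
    ss = np.random.SeedSequence(seed)
    plan = [(ctrl, 1)] * n_control + [(preset, 2)] * n_drought
    samples = []
    for i, (child, (pr, label)) in enumerate(zip(ss.spawn(len(plan)), plan)):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        spec_i = RosetteSpec(**{**rosette.__dict__, "seed": s})
        mask, _, _ = generate_rosette(spec_i)
        truth = make_truth(mask, pr, base_config=base_config, seed=s + 1)
        noise_i = NoiseModel(read_sd=noise.read_sd, shot_scale=noise.shot_scale, seed=s + 2)
        samples.append(
            CohortSample(
                plant_id=f"pot{i:03d}",
                label=label,
                preset_name=pr.name,
                seed=s,
                truth=truth,
                stack=simulate_stack(truth, protocol, noise_i),
                multicolor=simulate_multicolor(truth, noise_i),
            )
        )
    return samples


def cohort_manifest(samples: list[CohortSample]):
    """Cohort bookkeeping (plant id, label, preset, seed) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"plant_id": s.plant_id, "label": s.label, "preset": s.preset_name, "seed": s.seed}
            for s in samples
        ]
    )
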