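"""Base fluorescence signals and the derived parameter catalogue.

Locates the base signals (Fo, Fm, Fp, and the pre-flash/flash-maximum pairs
at every saturating flash) on a kinetic trace and computes the full
chlorophyll catalogue (89 named parameters) plus the 16 multicolor
parameters (4 band means and their 12 ordered pairwise ratios), i.e. 105
parameters per sample.

Formulae
--------
Fv/Fm        = (Fm - Fo) / Fm
NPQ_x        = (Fm - Fm_x) / Fm_x
Rfd_Ln       = (Fp - Ft_Ln) / Ft_Ln
PhiPSII_x    = (Fm_x - Ft_x) / Fm_x
qN_x         = (Fm - Fm_x) / (Fm - Fo_x)
qP_x         = (Fm_x - Ft_x) / (Fm_x - Fo_x)
qL_x printed = qP_x / (Fo_x / Ft_x)        (as-printed form; the
qL_x standard= qP_x * (Fo_x / Ft_x)         conventional lake-model form)

Fo_x (the light/relaxation-adapted minimal fluorescence) is not measured
by the protocol and is estimated with the Oxborough-Baker relation
Fo' = Fo / (Fv/Fm + Fo/Fm'), unless measured values are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .imaging import KineticTrace
from .protocol import ALL_STAGES, ProtocolDefinition, validate_protocol

__all__ = [
    "BasicSignals",
    "ParameterSet",
    "MulticolorSignals",
    "extract_basic_signals",
    "extract_basic_signals_pixelwise",
    "estimate_fo_prime",
    "fv_fm",
    "npq",
    "rfd",
    "phi_psii",
    "qn",
    "qp",
    "ql",
    "compute_catalogue",
    "extract_multicolor_signals",
    "multicolor_parameters",
    "catalogue_names",
    "CATALOGUE_VERSION",
]

CATALOGUE_VERSION = "v1"

_RFD_STAGES = ("L1", "L2", "L3", "L4")


@dataclass
class BasicSignals:
    """Measured base fluorescence levels, keyed by label.

    Values may be scalars (canopy means) or per-pixel arrays; all derived
    parameters broadcast. Keys: ``Fo``, ``Fm``, ``Fv``, ``Fp`` plus
    ``Ft_x``, ``Fm_x``, ``Fo_x``, ``Fv_x`` for each stage x in L1..L4,
    Lss, D1..D3.
    """

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        try:
            return self.values[key]
        except KeyError:
            raise KeyError(f"missing base signal {key!r}")

    def __contains__(self, key):
        return key in self.values

    def get(self, key, default=None):
        return self.values.get(key, default)

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(s for s in ALL_STAGES if f"Fm_{s}" in self.values)


@dataclass
class ParameterSet:
    """Named catalogue values (or maps)."""

    values: dict
    catalogue_version: str = CATALOGUE_VERSION

    def __getitem__(self, key):
        return self.values[key]

    def __len__(self):
        return len(self.values)

    def names(self) -> list[str]:
        return list(self.values)


@dataclass
class MulticolorSignals:
    """Mean UV-excited band emissions (each the mean of 5 exposures)."""

    BF: float
    GF: float
    RF: float
    IrF: float


# ---------------------------------------------------------------------------
# signal location on a trace

def _signals_from_series(times, values, state, p: ProtocolDefinition) -> BasicSignals:
    """Shared extraction for canopy-mean (values: (n,)) and per-pixel
    (values: (n, npix)) series."""
    violations = validate_protocol(p)
    if violations:
        raise ValueError(f"invalid protocol: {violations[0]}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out: dict = {}

    fo_start, fo_dur_ms = p.fo_window
    sel = (times >= fo_start) & (times <= fo_start + fo_dur_ms / 1000.0) & (state == "dark")
    if not sel.any():
        raise ValueError("trace has no frames in the Fo measuring window")
    out["Fo"] = values[sel].mean(axis=0)

    light_flashes = p.saturating_flashes("light")

    for ev in p.saturating_flashes():
        in_win = (times >= ev.time_s) & (times < ev.end_s)
        if not in_win.any():
            raise ValueError(
                f"trace has no frames in the flash window at {ev.time_s} s "
                "(trace truncated or protocol mismatch)"
            )
        peak = values[in_win].max(axis=0)
        for label in ev.yields:
            if label.startswith("Fm"):
                out[label] = peak
            elif label.startswith("Ft"):
                pre = (times >= ev.time_s - 1.0) & (times < ev.time_s) & (state != "saturating")
                if not pre.any():
                    raise ValueError(f"no pre-flash frames for {label}")
                if label == "Ft_Lss":
                    # the transient has settled: take the last pre-flash sample
                    out[label] = values[pre][-1]
                else:
                    out[label] = values[pre].mean(axis=0)

    if "Fm" not in out:
        raise ValueError("protocol has no Fm flash")
    out["Fv"] = out["Fm"] - out["Fo"]

    first_light = light_flashes[0].time_s if light_flashes else p.actinic_off_s
    fp_sel = (times > p.actinic_on_s) & (times < first_light) & (state == "actinic")
    if not fp_sel.any():
        raise ValueError("trace has no frames in the Fp window (actinic onset to first flash)")
    out["Fp"] = values[fp_sel].max(axis=0)

    if np.any(out["Fm"] < out["Fo"]):
        warnings.warn("Fm < Fo: implausible dark-adapted signals", stacklevel=2)
    stages = [k.split("_", 1)[1] for k in out if k.startswith("Fm_")]
    for stage in stages:
        fm_x = out[f"Fm_{stage}"]
        if np.any(fm_x > out["Fm"]):
            warnings.warn(f"Fm_{stage} exceeds Fm: implausible quenching", stacklevel=2)
        out[f"Fo_{stage}"] = estimate_fo_prime(out["Fo"], out["Fm"], fm_x)
        out[f"Fv_{stage}"] = fm_x - out[f"Fo_{stage}"]
    return BasicSignals(values=out)


def extract_basic_signals(trace: KineticTrace, p: ProtocolDefinition) -> BasicSignals:
    """Locate all base signals on a canopy-mean kinetic trace.

    Fo is the mean over the measuring window, each Fm-type signal the
    maximum within its flash window, Ft_Ln/Ft_Dn the mean of the 1 s
    pre-flash window, Ft_Lss the last pre-flash sample, and Fp the maximum
    of the actinic transient before the first light flash.
    """
    return _signals_from_series(trace.times_s, trace.mean_counts, trace.light_state, p)


def extract_basic_signals_pixelwise(stack, mask, p: ProtocolDefinition) -> BasicSignals:
    """As :func:`extract_basic_signals` but per pixel: every signal is an
    array over the mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return _signals_from_series(
        stack.times_s, stack.frames[:, mask], stack.light_state, p
    )


# ---------------------------------------------------------------------------
# elementary parameters

def estimate_fo_prime(Fo, Fm, Fm_prime):
    """Oxborough-Baker estimate of the light-adapted minimal fluorescence:
    Fo' = Fo / (Fv/Fm + Fo/Fm')."""
    Fo, Fm, Fm_prime = map(np.asarray, (Fo, Fm, Fm_prime))
    if np.any(Fm <= 0) or np.any(Fm_prime <= 0):
        raise ValueError("Fm and Fm' must be positive")
    denom = (Fm - Fo) / Fm + Fo / Fm_prime
    if np.any(denom <= 0):
        raise ValueError("nonpositive denominator in Fo' estimate")
    out = Fo / denom
    return float(out) if out.ndim == 0 else out


def _ret(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


def fv_fm(s: BasicSignals):
    """Maximum quantum yield of PSII photochemistry, (Fm - Fo)/Fm."""
    Fm = np.asarray(s["Fm"])
    if np.any(Fm <= 0):
        raise ValueError("Fm must be positive")
    return _ret((Fm - s["Fo"]) / Fm)


def npq(s: BasicSignals, stage: str):
    """Non-photochemical quenching at a stage, (Fm - Fm_x)/Fm_x."""
    fm_x = np.asarray(s[f"Fm_{stage}"])
    if np.any(fm_x <= 0):
        raise ValueError(f"Fm_{stage} must be positive")
    return _ret((s["Fm"] - fm_x) / fm_x)


def rfd(s: BasicSignals, n: str):
    """Fluorescence decline ratio in light, (Fp - Ft_Ln)/Ft_Ln."""
    stage = n if isinstance(n, str) else f"L{n}"
    ft = np.asarray(s[f"Ft_{stage}"])
    if np.any(ft <= 0):
        raise ValueError(f"Ft_{stage} must be positive")
    val = (s["Fp"] - ft) / ft
    if np.any(np.asarray(val) < 0):
        warnings.warn(f"Rfd_{stage} is negative (Ft above Fp)", stacklevel=2)
    return _ret(val)


def phi_psii(s: BasicSignals, stage: str):
    """PSII operating efficiency at a stage, (Fm_x - Ft_x)/Fm_x."""
    fm_x = np.asarray(s[f"Fm_{stage}"])
    if np.any(fm_x <= 0):
        raise ValueError(f"Fm_{stage} must be positive")
    return _ret((fm_x - s[f"Ft_{stage}"]) / fm_x)


def qn(s: BasicSignals, stage: str):
    """Coefficient of non-photochemical quenching, (Fm - Fm_x)/(Fm - Fo_x)."""
    denom = np.asarray(s["Fm"] - s[f"Fo_{stage}"])
    if np.any(denom == 0):
        raise ValueError(f"Fm equals Fo_{stage}: qN undefined")
    return _ret((s["Fm"] - s[f"Fm_{stage}"]) / denom)


def qp(s: BasicSignals, stage: str):
    """Coefficient of photochemical quenching, (Fm_x - Ft_x)/(Fm_x - Fo_x)."""
    denom = np.asarray(s[f"Fm_{stage}"] - s[f"Fo_{stage}"])
    if np.any(denom == 0):
        raise ValueError(f"Fm_{stage} equals Fo_{stage}: qP undefined")
    return _ret((s[f"Fm_{stage}"] - s[f"Ft_{stage}"]) / denom)


def ql(s: BasicSignals, stage: str, form: str = "printed"):
    """Lake-model photochemical quenching coefficient.

    ``form="printed"`` divides qP by Fo_x/Ft_x (the as-published form);
    ``form="standard"`` multiplies (the conventional definition,
    qL = qP * Fo'/Ft'). The two coincide when Ft = Fo'.
    """
    ft = np.asarray(s[f"Ft_{stage}"])
    if np.any(ft <= 0):
        raise ValueError(f"Ft_{stage} must be positive")
    ratio = s[f"Fo_{stage}"] / ft
    base = qp(s, stage)
    if form == "printed":
        return _ret(base / ratio)
    if form == "standard":
        return _ret(base * ratio)
    raise ValueError(f"unknown qL form {form!r}")


# ---------------------------------------------------------------------------
# catalogues

def catalogue_names(ql_form: str = "printed") -> list[str]:
    """Names of the 89 entries in the default chlorophyll catalogue:
    36 base signals plus 53 derived parameters."""
    names = ["Fo", "Fm", "Fv", "Fp"]
    for stage in ALL_STAGES:
        names += [f"Ft_{stage}", f"Fm_{stage}", f"Fo_{stage}", f"Fv_{stage}"]
    names.append("Fv/Fm")
    for stage in ALL_STAGES:
        names += [
            f"Fv'/Fm'_{stage}",
            f"NPQ_{stage}",
            f"qN_{stage}",
            f"qP_{stage}",
            f"qL_{stage}",
            f"PhiPSII_{stage}",
        ]
    names += [f"Rfd_{stage}" for stage in _RFD_STAGES]
    return names


def compute_catalogue(s: BasicSignals, ql_form: str = "printed") -> ParameterSet:
    """Compute the default 89-entry chlorophyll parameter catalogue.

    Composition: 36 base values (Fo, Fm, Fv, Fp and Ft/Fm/Fo/Fv at each of
    the 8 stages) and 53 derived (Fv/Fm; Fv'/Fm', NPQ, qN, qP, qL and
    PhiPSII at each stage; Rfd at L1-L4). Raises ``KeyError`` naming the
    first missing base signal.
    """
    vals: dict = {}
    for name in ("Fo", "Fm", "Fv", "Fp"):
        vals[name] = s[name]
    for stage in ALL_STAGES:
        for prefix in ("Ft", "Fm", "Fo", "Fv"):
            key = f"{prefix}_{stage}"
            vals[key] = s[key]
    vals["Fv/Fm"] = fv_fm(s)
    for stage in ALL_STAGES:
        fm_x = s[f"Fm_{stage}"]
        vals[f"Fv'/Fm'_{stage}"] = _ret((np.asarray(fm_x) - s[f"Fo_{stage}"]) / np.asarray(fm_x))
        vals[f"NPQ_{stage}"] = npq(s, stage)
        vals[f"qN_{stage}"] = qn(s, stage)
        vals[f"qP_{stage}"] = qp(s, stage)
        vals[f"qL_{stage}"] = ql(s, stage, form=ql_form)
        vals[f"PhiPSII_{stage}"] = phi_psii(s, stage)
    for stage in _RFD_STAGES:
        vals[f"Rfd_{stage}"] = rfd(s, stage)
    return ParameterSet(values=vals)


def extract_multicolor_signals(stack, mask) -> MulticolorSignals:
    """Band means over the mask: each band is the pixelwise average of its
    exposures, then averaged over the ROI."""
    mask = np.asarray(mask, dtype=bool)
    bands = stack.meta.get("bands")
    if bands is None:
        raise ValueError("stack has no band labels in meta['bands']")
    bands = np.asarray(bands)
    means = {}
    for band in ("BF", "GF", "RF", "IrF"):
        sel = bands == band
        if not sel.any():
            raise ValueError(f"no frames for band {band}")
        means[band] = float(stack.frames[sel].mean(axis=0)[mask].mean())
    return MulticolorSignals(**means)


def multicolor_parameters(m: MulticolorSignals) -> ParameterSet:
    """The 16 multicolor parameters: BF, GF, RF, IrF and all 12 ordered
    pairwise ratios (BF/GF, GF/BF, ...)."""
    bands = {"BF": m.BF, "GF": m.GF, "RF": m.RF, "IrF": m.IrF}
    for name, v in bands.items():
        if not np.all(np.asarray(v) > 0):
            raise ValueError(f"band {name} must be positive to form ratios")
    vals = dict(bands)
    for a, b in permutations(bands, 2):
        vals[f"{a}/{b}"] = bands[a] / bands[b]
    return ParameterSet(values=vals, catalogue_version=CATALOGUE_VERSION)
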