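"""Quenching-kinetics acquisition protocol.

The protocol is the timed schedule of measuring light, saturating flashes,
and actinic illumination that the forward simulator renders and the signal
extractor inverts. The default reproduces a dark-adapted Fo window, an Fm
saturating flash at 5.56 s, 70 s of actinic light with five saturating
flashes (L1-L4 and Lss at steady state), and three dark-relaxation flashes
(D1-D3).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import yaml

__all__ = [
    "FlashEvent",
    "ProtocolDefinition",
    "default_quenching_protocol",
    "validate_protocol",
    "base_signal_labels",
    "protocol_to_dict",
    "protocol_from_dict",
    "save_protocol",
    "load_protocol",
    "LIGHT_STAGES",
    "DARK_STAGES",
    "ALL_STAGES",
]

#: Stage suffixes for the saturating flashes under actinic light. The fifth
#: flash samples the steady state and is labelled "Lss" rather than "L5".
LIGHT_STAGES: tuple[str, ...] = ("L1", "L2", "L3", "L4", "Lss")

#: Stage suffixes for the dark-relaxation flashes.
DARK_STAGES: tuple[str, ...] = ("D1", "D2", "D3")

ALL_STAGES: tuple[str, ...] = LIGHT_STAGES + DARK_STAGES

_PHASES = ("dark_adapted", "light", "dark_relax")
_KINDS = ("measuring", "saturating")


@dataclass(frozen=True)
class FlashEvent:
    """A single timed light event.

    Parameters
    ----------
    time_s : float
        Event onset, seconds from protocol start.
    duration_ms : float
        Event duration in milliseconds.
    intensity_umol : float
        Photon flux density in umol m^-2 s^-1.
    kind : str
        ``"measuring"`` (weak, non-actinic) or ``"saturating"``.
    phase : str
        Protocol phase the event belongs to: ``"dark_adapted"``,
        ``"light"`` or ``"dark_relax"``.
    yields : tuple of str
        Base-signal labels produced by this event, e.g. ``("Ft_L1",
        "Fm_L1")`` for a light-phase saturating flash (pre-flash transient
        plus flash maximum).
    """

    time_s: float
    duration_ms: float
    intensity_umol: float
    kind: str
    phase: str
    yields: tuple[str, ...] = ()

    @property
    def end_s(self) -> float:
        return self.time_s + self.duration_ms / 1000.0


@dataclass
class ProtocolDefinition:
    """Full acquisition timeline for one quenching measurement."""

    dark_adapt_end_s: float = 17.0
    fo_window: tuple[float, float] = (1.0, 4040.0)  # (start_s, duration_ms)
    actinic_on_s: float = 22.24
    actinic_off_s: float = 92.24
    actinic_intensity_umol: float = 100.0
    fp_time_s: float = 23.12
    flashes: tuple[FlashEvent, ...] = ()
    frame_rate_hz: float = 2.0
    flash_frame_rate_hz: float = 50.0

    @property
    def fm_flash(self) -> FlashEvent:
        """The dark-adapted saturating flash that yields Fm."""
        for ev in self.flashes:
            if "Fm" in ev.yields:
                return ev
        raise ValueError("protocol has no Fm flash")

    def saturating_flashes(self, phase: str | None = None) -> list[FlashEvent]:
        out = [ev for ev in self.flashes if ev.kind == "saturating"]
        if phase is not None:
            out = [ev for ev in out if ev.phase == phase]
        return out

    @property
    def end_s(self) -> float:
        return max(ev.end_s for ev in self.flashes) if self.flashes else 0.0


def default_quenching_protocol(
    actinic_on_s: float = 22.24,
    fo_start_s: float = 1.0,
    frame_rate_hz: float = 2.0,
    flash_frame_rate_hz: float = 50.0,
) -> ProtocolDefinition:
    """Build the default quenching protocol.

    Fo is measured with a 4040 ms weak flash inside the initial dark
    window, Fm with a 320 ms saturating flash at 5.56 s; actinic light
    (100 umol m^-2 s^-1) runs for 70 s with saturating flashes at 32.24,
    42.24, 52.24, 72.24 and 92.24 s (L1-L4, Lss), Fp sampled at 23.12 s;
    dark-relaxation flashes at 122.24, 152.24 and 182.24 s (D1-D3).
    """
    actinic_off_s = actinic_on_s + 70.0
    sat = dict(duration_ms=320.0, intensity_umol=2300.0, kind="saturating")
    flashes = [
        FlashEvent(
            time_s=fo_start_s,
            duration_ms=4040.0,
            intensity_umol=0.1,
            kind="measuring",
            phase="dark_adapted",
            yields=("Fo",),
        ),
        FlashEvent(time_s=5.56, phase="dark_adapted", yields=("Fm",), **sat),
    ]
    light_times = (32.24, 42.24, 52.24, 72.24, 92.24)
    for t, stage in zip(light_times, LIGHT_STAGES):
        flashes.append(
            FlashEvent(
                time_s=t,
                phase="light",
                yields=(f"Ft_{stage}", f"Fm_{stage}"),
                **sat,
            )
        )
    dark_times = (122.24, 152.24, 182.24)
    for t, stage in zip(dark_times, DARK_STAGES):
        flashes.append(
            FlashEvent(
                time_s=t,
                phase="dark_relax",
                yields=(f"Ft_{stage}", f"Fm_{stage}"),
                **sat,
            )
        )
    return ProtocolDefinition(
        dark_adapt_end_s=17.0,
        fo_window=(fo_start_s, 4040.0),
        actinic_on_s=actinic_on_s,
        actinic_off_s=actinic_off_s,
        actinic_intensity_umol=100.0,
        fp_time_s=23.12,
        flashes=tuple(flashes),
        frame_rate_hz=frame_rate_hz,
        flash_frame_rate_hz=flash_frame_rate_hz,
    )


def _phase_of(p: ProtocolDefinition, t: float) -> str:
    """Phase at time ``t``; the light phase is the half-open-on-the-left
    interval (actinic_on, actinic_off], so a flash fired at actinic-off
    (the steady-state flash) still counts as light."""
    if t <= p.actinic_on_s:
        return "dark_adapted"
    if t <= p.actinic_off_s:
        return "light"
    return "dark_relax"


def validate_protocol(p: ProtocolDefinition) -> list[str]:
    """Check protocol invariants; returns a list of violation messages
    (empty when the protocol is valid). Violations are data, not errors."""
    v: list[str] = []
    if p.actinic_off_s <= p.actinic_on_s:
        v.append("actinic_off_s: must exceed actinic_on_s")
    prev_t = None
    for i, ev in enumerate(p.flashes):
        tag = f"flashes[{i}]"
        if ev.time_s < 0:
            v.append(f"{tag}.time_s: must be >= 0")
        if ev.duration_ms <= 0:
            v.append(f"{tag}.duration_ms: must be > 0")
        if ev.kind not in _KINDS:
            v.append(f"{tag}.kind: unknown kind {ev.kind!r}")
        if ev.phase not in _PHASES:
            v.append(f"{tag}.phase: unknown phase {ev.phase!r}")
        if ev.kind == "saturating" and ev.intensity_umol <= p.actinic_intensity_umol:
            v.append(f"{tag}.intensity_umol: saturating flash must exceed actinic intensity")
        if prev_t is not None and ev.time_s <= prev_t:
            v.append(f"{tag}.time_s: flash times must be strictly increasing")
        prev_t = ev.time_s
        if ev.phase in _PHASES and _phase_of(p, ev.time_s) != ev.phase:
            v.append(f"{tag}.phase: time {ev.time_s} s lies outside declared phase {ev.phase!r}")
    labels = [lab for ev in p.flashes for lab in ev.yields]
    dup = {lab for lab in labels if labels.count(lab) > 1}
    if dup:
        v.append(f"flashes.yields: duplicate labels {sorted(dup)}")
    if p.frame_rate_hz <= 0:
        v.append("frame_rate_hz: must be > 0")
    return v


def base_signal_labels(p: ProtocolDefinition) -> list[str]:
    """Ordered base-signal labels measured by protocol ``p``.

    For the default protocol: Fo, Fm, Fp, then the pre-flash transient and
    flash maximum for each light flash (Ft_L1..Ft_Lss, Fm_L1..Fm_Lss) and
    each dark-relaxation flash (Ft_D1..D3, Fm_D1..D3) — 19 labels.
    """
    violations = validate_protocol(p)
    if violations:
        raise ValueError(f"invalid protocol: {violations[0]}")
    labels: list[str] = []
    for ev in p.flashes:
        labels.extend(ev.yields)
    # Fp is sampled from the actinic transient, not from a flash event.
    if p.fp_time_s is not None and "Fm" in labels:
        labels.insert(labels.index("Fm") + 1, "Fp")
    return labels


# ---------------------------------------------------------------------------
# serialization

def protocol_to_dict(p: ProtocolDefinition) -> dict:
    d = dataclasses.asdict(p)
    d["fo_window"] = list(p.fo_window)
    d["flashes"] = [
        {**dataclasses.asdict(ev), "yields": list(ev.yields)} for ev in p.flashes
    ]
    return d


def protocol_from_dict(d: dict) -> ProtocolDefinition:
    flashes = tuple(
        FlashEvent(**{**ev, "yields": tuple(ev.get("yields", ()))})
        for ev in d.get("flashes", [])
    )
    kwargs = {k: v for k, v in d.items() if k not in ("flashes", "fo_window")}
    return ProtocolDefinition(
        fo_window=tuple(d.get("fo_window", (1.0, 4040.0))),
        flashes=flashes,
        **kwargs,
    )


def save_protocol(p: ProtocolDefinition, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"protocol": protocol_to_dict(p)}, fh, sort_keys=False)


def load_protocol(path) -> ProtocolDefinition:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return protocol_from_dict(d["protocol"] if "protocol" in d else d)
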