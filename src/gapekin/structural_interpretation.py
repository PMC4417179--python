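"""Distance conversion and structural-mode discrimination.

FRET efficiencies are converted to donor–acceptor distances through the
Förster relation E = 1 / (1 + (R/R0)^6) with R0 = 5.9 nm for the Cy3/Cy5
pair (computed under the kappa-squared = 2/3 isotropic-averaging
assumption, so absolute distances are approximate; *differences* between
states cancel the unknown linker offset and are quantitative).  The mode
classifier encodes the sign logic that discriminates gaping from
breathing, sliding and tightening/loosening using FRET probes placed at a
central, an upstream and a downstream position on the nucleosomal DNA
turns.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "FoersterModel",
    "ProbeObservation",
    "Sign",
    "Timescale",
    "Mode",
    "InsufficientEvidenceError",
    "fret_to_distance",
    "distance_to_fret",
    "gaping_amplitude",
    "classify_mode",
]


@dataclass(frozen=True)
class FoersterModel:
    """Förster conversion parameters for the dye pair.

    ``r0_nm`` assumes isotropic dye orientation (kappa^2 = 2/3);
    ``linker_allowance_nm`` is the plausible extension the C6 dye linkers
    add to *absolute* distances.  It is annotation only — never applied to
    distance differences, which are linker-independent.
    """

    r0_nm: float = 5.9
    kappa_squared: float = 2.0 / 3.0
    linker_allowance_nm: float = 2.2

    def __post_init__(self) -> None:
        if self.r0_nm <= 0:
            raise ValueError("R0 must be > 0")


class Sign(str, Enum):
    """Direction of the salt-induced FRET change at one probe."""

    INCREASE = "increase"
    DECREASE = "decrease"
    NONE = "none"


class Timescale(str, Enum):
    """Transition timescale: milliseconds (breathing) vs minutes (gaping)."""

    MS_SCALE = "ms_scale"
    MIN_SCALE = "min_scale"


class Mode(str, Enum):
    GAPING = "gaping"
    BREATHING = "breathing"
    SLIDING = "sliding"
    TIGHTENING_LOOSENING = "tightening_loosening"


class InsufficientEvidenceError(ValueError):
    """Required probe roles are missing from the observation set."""


@dataclass(frozen=True)
class ProbeObservation:
    """Salt-response of one labelling geometry.

    ``probe``: geometric role of the donor position relative to the shared
    acceptor — "center", "upstream" or "downstream".
    """

    probe: str
    sign: Sign
    timescale: Timescale

    def __post_init__(self) -> None:
        object.__setattr__(self, "sign", Sign(self.sign))
        object.__setattr__(self, "timescale", Timescale(self.timescale))


def fret_to_distance(e: float, model: FoersterModel = FoersterModel()) -> float:
    """Donor–acceptor distance (nm) from FRET efficiency.

    R = R0 * ((1 - E) / E)^(1/6); defined for 0 < E < 1.
    """
    if not (0 < e < 1):
        raise ValueError(f"FRET efficiency must be in (0, 1), got {e}")
    return model.r0_nm * ((1.0 - e) / e) ** (1.0 / 6.0)


def distance_to_fret(r_nm: float, model: FoersterModel = FoersterModel()) -> float:
    """FRET efficiency from donor–acceptor distance: E = 1/(1 + (R/R0)^6)."""
    if r_nm <= 0:
        raise ValueError(f"distance must be > 0, got {r_nm}")
    return 1.0 / (1.0 + (r_nm / model.r0_nm) ** 6)


def gaping_amplitude(
    state_fret: Mapping[str, float], model: FoersterModel = FoersterModel()
) -> tuple[dict[tuple[str, str], float], float]:
    """Pairwise distance changes between the gaping states.

    Returns (adjacent_pairs, extreme) in nm: the distance differences
    between consecutive states (ordered by decreasing E, i.e. increasing
    distance) and between the two extreme states.  No linker correction is
    applied — differences cancel the unknown constant offset, so they are
    meaningful even though absolute distances are approximate.
    """
    if len(state_fret) < 2:
        raise ValueError("need at least two states")
    ordered = sorted(state_fret, key=state_fret.__getitem__, reverse=True)
    dist = {s: fret_to_distance(state_fret[s], model) for s in ordered}
    adjacent = {
        (a, b): dist[b] - dist[a] for a, b in zip(ordered[:-1], ordered[1:])
    }
    extreme = dist[ordered[-1]] - dist[ordered[0]]
    return adjacent, extreme


def classify_mode(observations: Iterable[ProbeObservation]) -> set[Mode]:
    """Structural modes consistent with a set of multi-probe observations.

    Rules:

    * *breathing* — DNA-end unwrapping is millisecond-scale and is
      favoured by salt in a way that lowers FRET: requires ms-scale
      kinetics and a salt-induced FRET decrease at every reporting probe.
    * *sliding* and *tightening/loosening* — in-plane motion moves the
      outer turn along the wrap, so the upstream and downstream probes
      must change FRET with opposite signs.
    * *gaping* — out-of-plane clam-shell motion changes all probe
      distances in the same direction on a minutes scale: requires the
      same (non-null) sign at every probe and min-scale kinetics.

    Returns every mode whose requirements are met (possibly empty).
    Upstream and downstream probes are mandatory.
    """
    obs = list(observations)
    by_probe = {o.probe: o for o in obs}
    if "upstream" not in by_probe or "downstream" not in by_probe:
        missing = {"upstream", "downstream"} - set(by_probe)
        raise InsufficientEvidenceError(
            f"missing required probe roles: {sorted(missing)}"
        )

    signs = [o.sign for o in obs]
    active = [s for s in signs if s != Sign.NONE]
    timescales = {o.timescale for o in obs}
    all_min = timescales == {Timescale.MIN_SCALE}
    all_ms = timescales == {Timescale.MS_SCALE}

    modes: set[Mode] = set()
    if all_ms and active and all(s == Sign.DECREASE for s in active):
        modes.add(Mode.BREATHING)
    up, down = by_probe["upstream"].sign, by_probe["downstream"].sign
    opposite = {up, down} == {Sign.INCREASE, Sign.DECREASE}
    if opposite:
        modes.add(Mode.SLIDING)
        modes.add(Mode.TIGHTENING_LOOSENING)
    same_sign = len(active) == len(signs) and len(set(active)) == 1
    if same_sign and all_min:
        modes.add(Mode.GAPING)
    return modes
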