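"""Background suppression: TOF gating and BGO anticoincidence.

The two cuts that define the archive's spectrum layers: a 10 ns
time-of-flight window keeps the prompt-gamma component and removes
time-uncorrelated background; the BGO anticoincidence shield vetoes
events whose companion deposit exceeds 225 keV and arrives after the
primary signal (Compton and escape events).  ``build_layers`` produces
the four event populations Raw / TOF / BGO / All with exact set
inclusion All = TOF-kept intersected with BGO-kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuppressionConfig", "apply_tof_cut", "apply_ac_cut", "build_layers"]


@dataclass(frozen=True)
class SuppressionConfig:
    """Cut parameters; the boundary conventions are fixed for
    reproducibility: the prompt window is inclusive at both ends and the
    anticoincidence cut rejects strictly above 225 keV."""

    tof_window_ns: tuple[float, float] = (0.0, 10.0)
    ac_cut_kev: float = 225.0

    def __post_init__(self):
        lo, hi = self.tof_window_ns
        if not hi > lo:
            raise ValueError("tof window must have positive width")
        if not self.ac_cut_kev > 0:
            raise ValueError("ac energy cut must be > 0")


def _require_columns(events, columns):
    missing = [c for c in columns if c not in events.columns]
    if missing:
        raise KeyError(f"event stream lacks column(s) {missing}")


def apply_tof_cut(events, config: SuppressionConfig | None = None):
    """Keep events inside the prompt time-of-flight window (inclusive)."""
    config = config or SuppressionConfig()
    _require_columns(events, ["tof_ns"])
    lo, hi = config.tof_window_ns
    tof = np.asarray(events["tof_ns"], dtype=float)
    return events[(tof >= lo) & (tof <= hi)]


def apply_ac_cut(events, config: SuppressionConfig | None = None):
    """Veto events with a companion deposit strictly above the cut that
    arrived after the primary signal; a deposit exactly at 225 keV is
    retained."""
    config = config or SuppressionConfig()
    _require_columns(events, ["ac_energy_kev", "ac_after_primary"])
    deposit = np.asarray(events["ac_energy_kev"], dtype=float)
    after = np.asarray(events["ac_after_primary"], dtype=bool)
    veto = after & (deposit > config.ac_cut_kev)
    return events[~veto]


def build_layers(events, config: SuppressionConfig | None = None) -> dict:
    """The four suppression layers as event subsets.

    Raw = everything, TOF = prompt-window survivors, BGO =
    anticoincidence survivors, All = both cuts; the inclusions
    All <= TOF <= Raw and All <= BGO <= Raw hold exactly by
    construction.
    """
    config = config or SuppressionConfig()
    tof = apply_tof_cut(events, config)
    bgo = apply_ac_cut(events, config)
    both = apply_ac_cut(tof, config)
    return {"Raw": events, "TOF": tof, "BGO": bgo, "All": both}
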