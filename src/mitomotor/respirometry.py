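"""Respiration states from injection-phased oxygen-consumption traces.

Isolated striatal mitochondria are assayed on a Seahorse XF96 with a
fixed injection schedule — substrate only, then ADP, oligomycin, FCCP,
and finally rotenone + antimycin A. The mean OCR within each phase maps
to the classical respiration states:

    State 2  — substrate only (membrane-potential-consuming processes)
    State 3  — ADP-stimulated, ATP-linked respiration
    State 4o — oligomycin-inhibited, proton leak
    State 3u — FCCP-uncoupled, maximal respiration

The rotenone + antimycin A plateau is non-mitochondrial oxygen
consumption and is subtracted from every state by default; states are
then normalized by the well's protein mass. The respiratory control
ratio RCR = State 3 / State 4o indexes coupling between substrate
oxidation and ATP synthesis. Wells (quintuplicate per mouse) are
averaged per mouse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASE_ORDER = ("substrate", "adp", "oligomycin", "fccp", "rot_aa")
STATE_PHASE = {"state2": "substrate", "state3": "adp",
               "state4o": "oligomycin", "state3u": "fccp"}
SUBSTRATES = ("pyruvate_malate", "succinate_rotenone")


@dataclass(frozen=True)
class OcrTrace:
    """Phase-labelled OCR measurements for one well."""

    well_id: str
    mouse_id: str
    substrate: str
    measurements: tuple  # of (cycle_index, phase, ocr)
    protein_ug: float

    def __post_init__(self) -> None:
        if self.protein_ug <= 0:
            raise ValueError(f"well {self.well_id}: protein_ug must be positive")
        phases = [ph for _, ph, _ in self.measurements]
        missing = [p for p in PHASE_ORDER if p not in phases]
        if missing:
            raise ValueError(f"well {self.well_id}: missing phase(s) {missing}")
        # phases must appear as contiguous blocks in injection order
        seen = [p for i, p in enumerate(phases) if i == 0 or phases[i - 1] != p]
        if seen != [p for p in PHASE_ORDER if p in seen] or len(seen) != len(set(seen)):
            raise ValueError(
                f"well {self.well_id}: phases out of injection order: {seen}"
            )


@dataclass
class RespirationStates:
    mouse_id: str
    substrate: str
    state2: float
    state3: float
    state3u: float
    state4o: float
    rcr: float  # NaN when state4o <= 0
    n_wells: int = 1
    qc_clamped: bool = False


def compute_states(trace: OcrTrace, subtract_nonmito: bool = True) -> RespirationStates:
    """Phase means -> non-mito subtraction -> protein normalization.

    Each state is the mean OCR over all cycles of its phase, minus the
    rotenone+antimycin-A (non-mitochondrial) mean when
    ``subtract_nonmito`` is set, divided by the well's protein mass.
    Negative corrected states are physically meaningless and clamp to 0
    with a QC flag.
    """
    by_phase: dict[str, list[float]] = {}
    for _, phase, ocr in trace.measurements:
        by_phase.setdefault(phase, []).append(float(ocr))
    means = {ph: float(np.mean(v)) for ph, v in by_phase.items()}
    nonmito = means["rot_aa"] if subtract_nonmito else 0.0

    clamped = False
    states = {}
    for state, phase in STATE_PHASE.items():
        val = (means[phase] - nonmito) / trace.protein_ug
        if val < 0:
            clamped = True
            val = 0.0
        states[state] = val
    if clamped:
        logger.warning("well %s: negative corrected state clamped to 0", trace.well_id)
    return RespirationStates(
        mouse_id=trace.mouse_id,
        substrate=trace.substrate,
        rcr=rcr_value(states["state3"], states["state4o"]),
        qc_clamped=clamped,
        **states,
    )


def rcr_value(state3: float, state4o: float) -> float:
    """Respiratory control ratio State 3 / State 4o; NaN when leak <= 0."""
    if state4o <= 0 or not np.isfinite(state4o):
        return math.nan
    return state3 / state4o


def rcr(states: RespirationStates) -> float:
    if states.state4o <= 0:
        logger.warning("mouse %s: state4o <= 0, RCR undefined", states.mouse_id)
        return math.nan
    return states.state3 / states.state4o


def aggregate_mouse(
    wells: Sequence[RespirationStates], rcr_mode: str = "per-well"
) -> RespirationStates:
    """Average replicate wells (typically quintuplicate) for one mouse.

    ``rcr_mode='per-well'`` averages each well's own State3/State4o
    ratio, respecting within-well pairing; ``'of-means'`` takes the
    ratio of the averaged states instead.
    """
    if not wells:
        raise ValueError("no wells to aggregate")
    ids = {w.mouse_id for w in wells}
    subs = {w.substrate for w in wells}
    if len(ids) != 1 or len(subs) != 1:
        raise ValueError("wells span multiple mice or substrates")
    mean = lambda attr: float(np.mean([getattr(w, attr) for w in wells]))
    s2, s3, s3u, s4o = (mean(a) for a in ("state2", "state3", "state3u", "state4o"))
    if rcr_mode == "per-well":
        ratios = [w.rcr for w in wells if np.isfinite(w.rcr)]
        r = float(np.mean(ratios)) if ratios else math.nan
    elif rcr_mode == "of-means":
        r = rcr_value(s3, s4o)
    else:
        raise ValueError(f"unknown rcr_mode {rcr_mode!r}")
    return RespirationStates(
        mouse_id=wells[0].mouse_id,
        substrate=wells[0].substrate,
        state2=s2,
        state3=s3,
        state3u=s3u,
        state4o=s4o,
        rcr=r,
        n_wells=len(wells),
        qc_clamped=any(w.qc_clamped for w in wells),
    )


def traces_from_frame(df: pd.DataFrame) -> list[OcrTrace]:
    """Build OcrTrace objects from a tidy frame
    (well_id, mouse_id, substrate, cycle, phase, ocr, protein_ug)."""
    traces = []
    for well, sub in df.groupby("well_id", sort=True):
        sub = sub.sort_values("cycle")
        protein = sub["protein_ug"].iloc[0]
        traces.append(
            OcrTrace(
                well_id=str(well),
                mouse_id=str(sub["mouse_id"].iloc[0]),
                substrate=str(sub["substrate"].iloc[0]),
                measurements=tuple(
                    (int(r.cycle), str(r.phase), float(r.ocr)) for r in sub.itertuples()
                ),
                protein_ug=float(protein),
            )
        )
    return traces


def states_table(
    traces: Sequence[OcrTrace],
    subtract_nonmito: bool = True,
    rcr_mode: str = "per-well",
) -> pd.DataFrame:
    """Per-mouse x substrate respiration-state table from well traces."""
    per_well: dict[tuple[str, str], list[RespirationStates]] = {}
    for t in traces:
        st = compute_states(t, subtract_nonmito=subtract_nonmito)
        per_well.setdefault((t.mouse_id, t.substrate), []).append(st)
    rows = []
    for (mouse, substrate), wells in sorted(per_well.items()):
        agg = aggregate_mouse(wells, rcr_mode=rcr_mode)
        rows.append(
            {
                "mouse_id": mouse,
                "substrate": substrate,
                "state2": agg.state2,
                "state3": agg.state3,
                "state3u": agg.state3u,
                "state4o": agg.state4o,
                "rcr": agg.rcr,
                "n_wells": agg.n_wells,
                "qc_clamped": agg.qc_clamped,
            }
        )
    return pd.DataFrame(rows)
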