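"""Sex-chromosome-complement inference from marker-gene expression.

Reported sex and sex-chromosome complement can disagree (sample swaps,
Klinefelter/Turner karyotypes, somatic loss of Y), so the complement is
inferred from the expression data itself: a panel of X-Y gametolog pairs
(DDX3X/Y, USP9X/Y, ZFX/Y, UTX/Y, PCDH11X/Y) votes on Y presence, and XIST —
the lncRNA driving X inactivation — marks the presence of more than one X.
No single Y gene is trusted on its own (individual gametologs pick up
misaligned X reads under a default reference), and SRY is reported but not
voted by default (it is essentially testis-specific). Samples whose evidence
is contradictory are surfaced as ambiguous, never coerced: expression alone
cannot resolve loss-of-Y, XXY-like or reactivated-X states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .expression_stats import ExprMatrix

DEFAULT_TAU_Y = 1.0
DEFAULT_TAU_X = 2.0


@dataclass
class MarkerPanel:
    """X-Y homolog marker panel plus XIST and SRY.

    ``y_markers`` and ``x_partners`` are paired in order. Missing markers in
    a given matrix are tolerated (and flagged on the calls) as long as at
    least two Y markers and XIST resolve.
    """

    y_markers: list[str] = field(
        default_factory=lambda: ["DDX3Y", "USP9Y", "ZFY", "UTY", "PCDH11Y"]
    )
    x_partners: list[str] = field(
        default_factory=lambda: ["DDX3X", "USP9X", "ZFX", "UTX", "PCDH11X"]
    )
    xist: str = "XIST"
    sry: str = "SRY"
    include_sry_in_vote: bool = False

    def __post_init__(self) -> None:
        if not self.y_markers:
            raise ValueError("marker panel needs at least one Y marker")
        if len(self.y_markers) != len(self.x_partners):
            raise ValueError("y_markers and x_partners must pair up in order")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump(
                {
                    "y_markers": self.y_markers,
                    "x_partners": self.x_partners,
                    "xist": self.xist,
                    "sry": self.sry,
                    "include_sry_in_vote": self.include_sry_in_vote,
                },
                sort_keys=False,
            )
        )
        return path


def default_panel() -> MarkerPanel:
    """The standard five-gametolog panel with XIST and (reporting-only) SRY."""
    return MarkerPanel()


@dataclass
class SccCall:
    """Per-sample inference result; the call is a pure function of the flags."""

    sample: str
    y_present: bool
    multi_x: bool
    call: str  # XY | XX | ambiguous_Y_and_XIST | ambiguous_neither
    marker_values: dict[str, float]
    tau_y: float
    tau_x: float
    missing_markers: list[str] = field(default_factory=list)


def _call_from_flags(y_present: bool, multi_x: bool) -> str:
    if y_present and not multi_x:
        return "XY"
    if multi_x and not y_present:
        return "XX"
    if y_present and multi_x:
        return "ambiguous_Y_and_XIST"
    return "ambiguous_neither"


def infer_scc(
    expr: ExprMatrix,
    panel: MarkerPanel | None = None,
    tau_y: float = DEFAULT_TAU_Y,
    tau_x: float = DEFAULT_TAU_X,
) -> list[SccCall]:
    """Call each sample's sex-chromosome complement from log2-CPM values.

    ``y_present`` is true iff a strict majority of the resolvable Y markers
    exceed ``tau_y`` log2-CPM; ``multi_x`` iff XIST exceeds ``tau_x``.
    XY = Y and a single X; XX = no Y and more than one X; contradictory or
    empty evidence yields an explicit ambiguous call. Thresholds are on the
    log2-CPM scale and therefore depend on the prior and on library size
    (the zero-count floor is log2(prior/L)); the defaults suit libraries of
    tens of millions of reads. Every call carries the per-marker values so a
    human can override.
    """
    panel = panel or default_panel()
    genes = set(expr.genes)
    if panel.xist not in genes:
        raise ValueError(f"XIST marker {panel.xist!r} not present in the matrix")
    vote_markers = list(panel.y_markers)
    if panel.include_sry_in_vote:
        vote_markers.append(panel.sry)
    avail_y = [m for m in vote_markers if m in genes]
    if len(avail_y) < 2:
        missing = [m for m in vote_markers if m not in genes]
        raise ValueError(
            f"need >=2 resolvable Y markers, have {len(avail_y)}; missing: {missing}"
        )
    report_genes = (
        panel.y_markers + panel.x_partners + [panel.xist, panel.sry]
    )
    missing = [m for m in report_genes if m not in genes]

    calls = []
    for sample in expr.samples:
        col = expr.values[sample]
        y_votes = sum(bool(col[m] > tau_y) for m in avail_y)
        y_present = y_votes * 2 > len(avail_y)
        multi_x = bool(col[panel.xist] > tau_x)
        values = {m: float(col[m]) for m in report_genes if m in genes}
        calls.append(
            SccCall(
                sample=sample,
                y_present=y_present,
                multi_x=multi_x,
                call=_call_from_flags(y_present, multi_x),
                marker_values=values,
                tau_y=tau_y,
                tau_x=tau_x,
                missing_markers=missing,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[SccCall]) -> pd.DataFrame:
    """Flatten calls (one row per sample, marker values as columns)."""
    rows = []
    for c in calls:
        row = {
            "sample": c.sample,
            "call": c.call,
            "y_present": c.y_present,
            "multi_x": c.multi_x,
            "tau_y": c.tau_y,
            "tau_x": c.tau_x,
        }
        row.update(c.marker_values)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def write_calls(calls: Sequence[SccCall], path: str | Path) -> Path:
    path = Path(path)
    calls_to_frame(calls).to_csv(path, sep="\t")
    return path
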