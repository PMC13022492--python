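"""The U-smile plot: four subclass points summarizing class-stratified model change.

Along the x-axis, in fixed order, sit the non-event improvement {+,0},
non-event worsening {-,0}, event worsening {-,1} and event improvement
{+,1} subclass coefficients (all non-negative).  A deep symmetric "smile"
means strong balanced improvement; large inner points flag worsening.
Point area scales with the I coefficient (the within-class share of
observations in that subclass); the two class lines are solid when the
class improvement is significant at ``alpha``, dashed otherwise, and
omitted entirely for non-parametric models where no test is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import ICoefficients, RLRCoefficients
from .exceptions import ValidationError
from .inference import SignificanceResult

NONEVENT_COLOR = "#1f77b4"  # blue role
EVENT_COLOR = "#d62728"  # red role
CENTRAL_COLOR = "#7f7f7f"  # gray central line, no test attached

#: Fixed x-axis order of the four subclasses.
SLOT_ORDER = ("{+,0}", "{-,0}", "{-,1}", "{+,1}")


@dataclass
class PlotPoint:
    x_slot: int  # 1..4
    subclass: str
    y: float  # subclass rLR coefficient (>= 0)
    size_weight: float  # I coefficient in [0, 1]
    color: str


@dataclass
class PlotLine:
    slots: tuple[int, int]
    style: str  # solid | dashed | absent
    color: str


@dataclass
class UsmilePlotSpec:
    """Pure-data description of one U-smile panel."""

    points: list[PlotPoint]
    nonevent_line: PlotLine
    event_line: PlotLine
    central_line: PlotLine
    alpha: Optional[float]
    asymmetry: float  # |rLR0 - rLR1|
    title: str = ""


def build_plot_spec(
    coeffs: RLRCoefficients,
    icoeffs: ICoefficients,
    sig: Optional[SignificanceResult] = None,
    alpha: float = 0.05,
    title: str = "",
) -> UsmilePlotSpec:
    """Map coefficient objects onto the fixed four-slot plot layout.

    ``sig=None`` (non-parametric model) renders both class lines absent.
    """
    ys = (coeffs.rLR0_plus, coeffs.rLR0_minus, coeffs.rLR1_minus, coeffs.rLR1_plus)
    ws = (icoeffs.I0_plus, icoeffs.I0_minus, icoeffs.I1_minus, icoeffs.I1_plus)
    colors = (NONEVENT_COLOR, NONEVENT_COLOR, EVENT_COLOR, EVENT_COLOR)
    points = [
        PlotPoint(x_slot=i + 1, subclass=SLOT_ORDER[i], y=float(ys[i]),
                  size_weight=float(ws[i]), color=colors[i])
        for i in range(4)
    ]

    def _style(solid: Optional[bool]) -> str:
        if solid is None:
            return "absent"
        return "solid" if solid else "dashed"

    return UsmilePlotSpec(
        points=points,
        nonevent_line=PlotLine((1, 2), _style(None if sig is None else sig.solid0), NONEVENT_COLOR),
        event_line=PlotLine((3, 4), _style(None if sig is None else sig.solid1), EVENT_COLOR),
        central_line=PlotLine((2, 3), "solid", CENTRAL_COLOR),
        alpha=None if sig is None else alpha,
        asymmetry=abs(coeffs.rLR0 - coeffs.rLR1),
        title=title,
    )


_MIN_AREA = 20.0  # pt^2, keeps zero-proportion points visible
_MAX_AREA = 600.0


def _draw(ax, spec: UsmilePlotSpec) -> None:
    for line in (spec.central_line, spec.nonevent_line, spec.event_line):
        if line.style == "absent":
            continue
        xs = list(line.slots)
        ys = [spec.points[s - 1].y for s in line.slots]
        ax.plot(xs, ys, linestyle="-" if line.style == "solid" else "--",
                color=line.color, zorder=1)
    for pt in spec.points:
        # marker *area* proportional to the I coefficient
        area = _MIN_AREA + pt.size_weight * (_MAX_AREA - _MIN_AREA)
        ax.scatter([pt.x_slot], [pt.y], s=area, color=pt.color, zorder=2)
    top = max(0.05, max(pt.y for pt in spec.points) * 1.2)
    ax.set_ylim(0.0, top)
    ax.set_xlim(0.5, 4.5)
    ax.set_xticks([1, 2, 3, 4], SLOT_ORDER)
    ax.set_ylabel("rLR coefficient")
    note = f"|rLR0 - rLR1| = {spec.asymmetry:.3f}"
    if spec.alpha is not None:
        note += f", alpha = {spec.alpha:g}"
    ax.set_title(f"{spec.title}\n{note}" if spec.title else note, fontsize=10)


def render(spec: UsmilePlotSpec | list[UsmilePlotSpec], path, format: str = "svg"):
    """Render one spec (or a sequence, as a grid of panels) to ``path``.

    Output is deterministic: identical specs produce identical bytes.
    """
    if format not in ("svg", "png"):
        raise ValidationError(f"format must be 'svg' or 'png', got {format!r}")
    specs = spec if isinstance(spec, list) else [spec]
    if not specs:
        raise ValidationError("nothing to render")
    ncols = min(2, len(specs))
    nrows = -(-len(specs) // ncols)
    with plt.rc_context({"svg.hashsalt": "usmile"}):
        fig, axes = plt.subplots(
            nrows, ncols, figsize=(4.5 * ncols, 3.5 * nrows), squeeze=False
        )
        for ax in axes.ravel():
            ax.set_visible(False)
        for ax, sp in zip(axes.ravel(), specs):
            ax.set_visible(True)
            _draw(ax, sp)
        fig.tight_layout()
        fig.savefig(path, format=format, metadata=_no_date_metadata(format))
        plt.close(fig)
    return path


def _no_date_metadata(format: str) -> dict | None:
    # strip the creation timestamp so identical specs give identical bytes
    return {"Date": None} if format == "svg" else None
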