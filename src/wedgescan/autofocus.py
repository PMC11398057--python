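"""Passive mountain-climbing autofocus.

Image sharpness is scored by the variance of a 3×3 Laplacian of the
grayscale capture: high variance means high spatial frequency, i.e. crisp
edges.  The search mimics an operator: start at the objective's nominal
working distance, probe ±2 default steps to pick a direction, then climb
from the starting height in half-steps for up to 15 climb captures and
return the height with the maximal score seen.  Running the climb to the
cap rather than halting at the first score drop is what defeats false
positives: far from focus the score is a noise plateau on which a single
drop is meaningless.

The two direction probes are compared against each other; an exact tie
(as on a featureless field) leaves the Z axis at the initial position.
Probe captures do not count toward the 15-capture climb cap, so the total
render budget is at most 18 (initial + 2 probes + 15 climbs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .specs import MagnificationSpec

__all__ = ["FocusTrace", "focus_score", "autofocus"]

MAX_CLIMB_CAPTURES = 15


def focus_score(image: np.ndarray) -> float:
    """Variance of the 3×3 Laplacian of the grayscale image.

    Invariant to constant offsets (the Laplacian kills DC); zero for a
    constant image; decreases under blur.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        image = image.mean(axis=-1)
    lap = ndimage.laplace(image)
    return float(lap.var())


@dataclass
class FocusTrace:
    """Record of one autofocus run: every (z, score) evaluation, the chosen
    height and the climb direction ('up', 'down' or 'none')."""

    evaluations: list[tuple[float, float]] = field(default_factory=list)
    chosen_z_um: float = float("nan")
    direction: str = "none"
    error: str | None = None

    @property
    def n_captures(self) -> int:
        return len(self.evaluations)

    def best(self) -> tuple[float, float]:
        return max(self.evaluations, key=lambda zs: zs[1])

    def to_json_records(self) -> list[dict]:
        recs = [{"z_um": z, "score": s} for z, s in self.evaluations]
        recs.append({"chosen_z_um": self.chosen_z_um, "direction": self.direction,
                     "n_captures": self.n_captures, "error": self.error})
        return recs


def autofocus(microscope, mag: MagnificationSpec) -> FocusTrace:
    """Run the mountain-climbing search at the microscope's current (x, y).

    The stage is left at the chosen height on success.  Manual controls are
    locked for the duration of the run and always released.  On a render
    failure mid-run the trace is returned with its ``error`` field set and
    the stage restored to the pre-run height.
    """
    trace = FocusTrace()
    step = mag.af_default_step_um
    z0 = mag.working_distance_um
    pre_run_z = microscope.pose.z_um
    microscope.lock_manual_controls()
    try:
        def evaluate(z: float) -> float:
            microscope.move_to(z_um=z)
            s = focus_score(microscope.capture_rgb(mag.factor))
            trace.evaluations.append((microscope.pose.z_um, s))
            return s

        evaluate(z0)
        up = evaluate(z0 + 2.0 * step)
        down = evaluate(z0 - 2.0 * step)

        if up == down:
            # no improvement in either direction: stay at the initial height
            trace.direction = "none"
            trace.chosen_z_um = microscope.move_to(z_um=z0).z_um
            return trace

        sign = 1.0 if up > down else -1.0
        trace.direction = "up" if sign > 0 else "down"
        climb = step / 2.0
        for k in range(1, MAX_CLIMB_CAPTURES + 1):
            evaluate(z0 + sign * k * climb)
        z_best, _ = trace.best()
        trace.chosen_z_um = microscope.move_to(z_um=z_best).z_um
        return trace
    except Exception as exc:  # render failure: restore and report
        trace.error = str(exc)
        microscope.move_to(z_um=pre_run_z)
        if not np.isnan(trace.chosen_z_um):
            trace.chosen_z_um = float("nan")
        return trace
    finally:
        microscope.release_manual_controls()
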