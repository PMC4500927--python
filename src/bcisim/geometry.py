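"""Default reach geometry: workspace box, target volume, and start position.

The simulated task is an outward reach from an armrest into a volume in front
of and above the hand.  The target volume is a box centred on the origin (the
origin sits at the centre of the volume containing the targets); the start
position lies below and behind it, outside the target volume but inside the
workspace box that commands are clamped to.  The geometry is calibrated so
that a quasi-uniform 33-target set has start-to-target distances spanning
roughly 28-69 cm with a mean near 48 cm.
"""

from __future__ import annotations

import numpy as np

from .submovements import Workspace

__all__ = ["default_workspace", "default_target_volume", "default_start_pos"]


def default_workspace() -> Workspace:
    """Box (cm) that commanded positions/goals are clamped into; contains the start."""
    return Workspace(low=(-30.0, -30.0, -45.0), high=(30.0, 20.0, 20.0))


def default_target_volume() -> Workspace:
    """Box (cm) that targets are drawn from, centred on the origin."""
    return Workspace(low=(-25.0, -15.0, -12.5), high=(25.0, 15.0, 12.5))


def default_start_pos() -> np.ndarray:
    """Hand start position (cm): below/behind the target volume, on the armrest."""
    return np.array([0.0, -25.0, -37.5])
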