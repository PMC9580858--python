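"""Per-channel intensity transfer: a monotonic quadratic parameterized by
dark/mid/bright levels, plus channel color and global opacity.

The mapping sends normalized voxel values in [0, 1] to emissive intensity
in [0, 1]: zero at or below ``i_dark``, one at or above ``i_bright``, and a
quadratic in between whose value at the midpoint ``(i_dark + i_bright) / 2``
equals ``i_mid``.  Monotonicity on the active interval requires the
midpoint output to lie in [0.25, 0.75]; requests outside that band are
clamped rather than rejected (slider semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ChannelTransfer",
    "TransferCoefficients",
    "MID_MIN",
    "MID_MAX",
    "clamp_mid",
    "solve_coefficients",
    "apply_transfer",
    "concavity",
    "default_transfers",
    "DEFAULT_COLORS",
]

log = logging.getLogger(__name__)

# Endpoint-derivative analysis of the normalized quadratic g(u) = A u^2 + B u
# with g(1) = 1 and g(1/2) = m gives g'(0) = 4m - 1 and g'(1) = 3 - 4m, so
# the quadratic is non-decreasing on [0, 1] exactly when m is in this band.
MID_MIN = 0.25
MID_MAX = 0.75

DEFAULT_COLORS: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),  # red
    (0.0, 1.0, 0.0),  # green
    (0.0, 0.0, 1.0),  # blue
    (1.0, 0.0, 1.0),  # magenta
    (1.0, 1.0, 0.0),  # yellow
    (0.0, 1.0, 1.0),  # cyan
)


def clamp_mid(i_mid: float) -> float:
    """Clamp the midpoint output into the monotone band [0.25, 0.75]."""
    return float(min(max(i_mid, MID_MIN), MID_MAX))


@dataclass(frozen=True)
class ChannelTransfer:
    """Dark/mid/bright transfer parameters plus color/alpha for one channel.

    ``i_mid`` is stored in effective (clamped) form so that a read-back
    after a set reports the value actually used.
    """

    i_dark: float = 0.0
    i_mid: float = 0.5
    i_bright: float = 1.0
    alpha: float = 1.0
    color: tuple[float, float, float] = (1.0, 0.0, 0.0)
    visible: bool = True

    def __post_init__(self):
        for name in ("i_dark", "i_bright", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if not self.i_dark < self.i_bright:
            raise InvalidParameterError(
                f"require i_dark < i_bright, got {self.i_dark} >= {self.i_bright}"
            )
        color = tuple(float(c) for c in self.color)
        if len(color) != 3 or any(not 0.0 <= c <= 1.0 for c in color):
            raise InvalidParameterError(f"color must be an RGB triple in [0, 1], got {self.color!r}")
        object.__setattr__(self, "i_mid", clamp_mid(float(self.i_mid)))
        object.__setattr__(self, "color", color)
        object.__setattr__(self, "i_dark", float(self.i_dark))
        object.__setattr__(self, "i_bright", float(self.i_bright))
        object.__setattr__(self, "alpha", float(self.alpha))

    def to_doc(self) -> dict:
        return {
            "dark": self.i_dark,
            "mid": self.i_mid,
            "bright": self.i_bright,
            "alpha": self.alpha,
            "color": list(self.color),
            "visible": self.visible,
        }

    @classmethod
    def from_doc(cls, doc: dict, base: "ChannelTransfer | None" = None) -> "ChannelTransfer":
        """Build from a (possibly partial) JSON document, defaulting missing
        fields from ``base``."""
        base = base or cls()
        known = {"dark", "mid", "bright", "alpha", "color", "visible"}
        unknown = set(doc) - known
        if unknown:
            raise InvalidParameterError(f"unknown transfer field {sorted(unknown)[0]!r}")
        return cls(
            i_dark=doc.get("dark", base.i_dark),
            i_mid=doc.get("mid", base.i_mid),
            i_bright=doc.get("bright", base.i_bright),
            alpha=doc.get("alpha", base.alpha),
            color=tuple(doc.get("color", base.color)),
            visible=bool(doc.get("visible", base.visible)),
        )


@dataclass(frozen=True)
class TransferCoefficients:
    """Coefficients of ``i_out = a*i_in**2 + b*i_in + c`` on [i_dark, i_bright]."""

    a: float
    b: float
    c: float

    def __call__(self, x):
        return self.a * np.square(x) + self.b * x + self.c


def solve_coefficients(t: ChannelTransfer) -> TransferCoefficients:
    """Solve the three interpolation constraints in closed form.

    f(i_dark) = 0, f(i_bright) = 1, f((i_dark + i_bright)/2) = i_mid.
    Working in the normalized variable u = (x - d)/(b - d), the solution is
    g(u) = A u^2 + B u with A = 2 - 4 m and B = 4 m - 1, mapped back to the
    original variable.  The clamped i_mid guarantees the result is
    non-decreasing on the active interval.
    """
    d, br = t.i_dark, t.i_bright
    if not d < br:
        raise InvalidParameterError(f"require i_dark < i_bright, got {d} >= {br}")
    m = clamp_mid(t.i_mid)
    A = 2.0 - 4.0 * m
    B = 4.0 * m - 1.0
    w = br - d
    a = A / (w * w)
    b = B / w - 2.0 * A * d / (w * w)
    c = A * d * d / (w * w) - B * d / w
    return TransferCoefficients(a=a, b=b, c=c)


def apply_transfer(t: ChannelTransfer, i_in):
    """Evaluate the transfer: 0 below dark, 1 above bright, quadratic
    between, output clamped to [0, 1].  Accepts scalars or arrays; inputs
    outside [0, 1] are clamped with a warning."""
    x = np.asarray(i_in, dtype=np.float64)
    if np.any(x < 0.0) or np.any(x > 1.0):
        log.warning("transfer input outside [0, 1]; clamping")
        x = np.clip(x, 0.0, 1.0)
    coef = solve_coefficients(t)
    out = np.clip(coef(x), 0.0, 1.0)
    out = np.where(x <= t.i_dark, 0.0, out)
    out = np.where(x >= t.i_bright, 1.0, out)
    if np.isscalar(i_in) or np.ndim(i_in) == 0:
        return float(out)
    return out


def concavity(t: ChannelTransfer) -> str:
    """Shape class of the quadratic: 'concave_down', 'linear' or 'concave_up'."""
    a = solve_coefficients(t).a
    if a < 0:
        return "concave_down"
    if a > 0:
        return "concave_up"
    return "linear"


def default_transfers(num_channels: int) -> list[ChannelTransfer]:
    """One default transfer per channel with cycling colors."""
    return [
        ChannelTransfer(color=DEFAULT_COLORS[i % len(DEFAULT_COLORS)])
        for i in range(num_channels)
    ]
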