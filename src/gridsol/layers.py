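"""Depth-layer remapping between template horizons and output layers.

Generic templates carry seven horizons (0-10, 10-30, 30-60, 60-90,
90-120, 120-150, 150-180 cm) while the gridded output uses the six
standard depth intervals (0-5, 5-15, 15-30, 30-60, 60-100, 100-200 cm).
Template-inherited per-layer values (root growth factor SRGF, total
nitrogen SLNI) are therefore remapped through a fixed weighted-average
scheme:

    0-5     <- horizon 1
    5-15    <- 0.5 x horizon 1 + 0.5 x horizon 2
    15-30   <- horizon 2
    30-60   <- horizon 3
    60-100  <- 0.75 x horizon 4 + 0.25 x horizon 5
    100-200 <- 0.2 x horizon 5 + 0.3 x horizon 6 + 0.5 x horizon 7

The 5-15 cm weights are the scheme's stated 0.5/0.5, not exact overlap
fractions.  The mapping is linear, conserves constants (weights sum to
one per output layer) and preserves monotone-non-increasing inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

STANDARD_LAYER_BOUNDS = ((0, 5), (5, 15), (15, 30), (30, 60), (60, 100), (100, 200))
STANDARD_SLB = tuple(b for _, b in STANDARD_LAYER_BOUNDS)

_WEIGHT_SUM_TOL = 1e-9


class LayerSchemeError(ValueError):
    """Invalid weight scheme or input arity."""


@dataclass(frozen=True)
class LayerWeightScheme:
    """For each of the 6 output layers, (1-based horizon index, weight)
    pairs.  Weights must lie in [0, 1] and sum to 1 per output layer."""

    weights: tuple[tuple[tuple[int, float], ...], ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(STANDARD_LAYER_BOUNDS):
            raise LayerSchemeError(
                f"scheme needs {len(STANDARD_LAYER_BOUNDS)} output layers, "
                f"got {len(self.weights)}"
            )
        for bounds, pairs in zip(STANDARD_LAYER_BOUNDS, self.weights):
            total = 0.0
            for idx, w in pairs:
                if not 1 <= idx <= 7:
                    raise LayerSchemeError(f"layer {bounds}: horizon index {idx} not in 1..7")
                if not (0.0 <= w <= 1.0):
                    raise LayerSchemeError(f"layer {bounds}: weight {w} outside [0, 1]")
                total += w
            if abs(total - 1.0) > _WEIGHT_SUM_TOL:
                raise LayerSchemeError(
                    f"layer {bounds}: weights sum to {total}, not 1"
                )

    @classmethod
    def from_config(cls, spec: Sequence[Sequence[Sequence[float]]]) -> "LayerWeightScheme":
        """Build from the nested-list form used in config files:
        ``[[[1, 1.0]], [[1, 0.5], [2, 0.5]], ...]``."""
        return cls(tuple(
            tuple((int(i), float(w)) for i, w in pairs) for pairs in spec
        ))


DEFAULT_SCHEME = LayerWeightScheme((
    ((1, 1.0),),
    ((1, 0.5), (2, 0.5)),
    ((2, 1.0),),
    ((3, 1.0),),
    ((4, 0.75), (5, 0.25)),
    ((5, 0.2), (6, 0.3), (7, 0.5)),
))


def remap_template_values(
    values_7: Sequence[float],
    scheme: LayerWeightScheme = DEFAULT_SCHEME,
    clamp_unit: bool = False,
) -> tuple[float, ...]:
    """Remap 7 per-horizon values onto the 6 standard output layers.

    ``clamp_unit=True`` clips the outputs to [0, 1] (for SRGF).
    """
    if len(values_7) != 7:
        raise LayerSchemeError(f"need exactly 7 horizon values, got {len(values_7)}")
    out = []
    for pairs in scheme.weights:
        v = sum(w * float(values_7[idx - 1]) for idx, w in pairs)
        if clamp_unit:
            v = min(1.0, max(0.0, v))
        out.append(v)
    return tuple(out)
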