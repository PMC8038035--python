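"""Minimal named-CRS model with a registry of affine transforms.

The pipeline operates in a single projected, metre-based CRS; reprojection
exists so that layers digitised in another named system can be brought into
it.  A CRS is just a string identifier.  Transforms between identifiers are
affine per-axis maps ``(x, y) -> (ax*x + bx, ay*y + by)`` looked up in a
registry; an unknown pair raises :class:`~firehia.errors.CRSError`.

Built-in identifiers:

``local-metre``
    Projected plane in metres (the native CRS of synthetic scenarios).
``local-km``
    The same plane in kilometres.
``local-degree``
    Equirectangular degrees about a reference latitude of 34° S (the NSW
    coast): 1° latitude = 111 320 m, 1° longitude = 111 320·cos(34°) m.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Tuple

from firehia.errors import CRSError

# metres per degree of latitude on the sphere (IUGG mean radius)
METRES_PER_DEGREE = 111_320.0
REFERENCE_LATITUDE = -34.0

AffineTransform = Tuple[float, float, float, float]  # ax, bx, ay, by

_REGISTRY: Dict[Tuple[str, str], AffineTransform] = {}


def register_transform(src: str, dst: str, ax: float, bx: float, ay: float, by: float) -> None:
    """Register ``(x, y) -> (ax*x + bx, ay*y + by)`` from *src* to *dst*.

    The inverse is registered automatically.
    """
    if ax == 0 or ay == 0:
        raise CRSError("degenerate transform: zero scale factor")
    _REGISTRY[(src, dst)] = (ax, bx, ay, by)
    _REGISTRY[(dst, src)] = (1.0 / ax, -bx / ax, 1.0 / ay, -by / ay)


def get_transform(src: str, dst: str) -> Callable[[float, float], Tuple[float, float]]:
    """Return a point-transform callable from *src* to *dst* CRS."""
    if src is None or dst is None:
        raise CRSError("undefined CRS")
    if src == dst:
        return lambda x, y: (x, y)
    try:
        ax, bx, ay, by = _REGISTRY[(src, dst)]
    except KeyError:
        raise CRSError(f"no registered transform {src!r} -> {dst!r}") from None
    return lambda x, y: (ax * x + bx, ay * y + by)


_cos_ref = math.cos(math.radians(REFERENCE_LATITUDE))
register_transform("local-metre", "local-km", 1e-3, 0.0, 1e-3, 0.0)
register_transform(
    "local-metre",
    "local-degree",
    1.0 / (METRES_PER_DEGREE * _cos_ref),
    0.0,
    1.0 / METRES_PER_DEGREE,
    0.0,
)
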