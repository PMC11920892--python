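"""Paddle contact layouts, affine registration, and normalized coordinates.

An epidural paddle is modelled as a planar grid of stimulation/recording
contacts.  The paddle frame puts the left-most caudal contact at the origin,
with ``x`` increasing to the animal's right (mediolateral) and ``y``
increasing rostrally.  Layouts can be registered to anatomy (e.g. a
radiograph landmark frame) with a least-squares affine transform, and contact
coordinates can be normalized to the half-open unit square ``[0, 1)^2`` —
the encoding consumed by the stimulation-parameter inference models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PaddleSpec",
    "PaddleLayout",
    "AffineTransform",
    "hd64_spec",
    "medtronic_565_layout",
    "build_layout",
    "fit_affine",
    "normalize_coords",
    "overlay_comparator",
    "NORM_EPS",
]

#: Relative inflation of the coordinate span used when normalizing, so that
#: the maximum coordinate maps strictly below 1 (half-open [0, 1) contract).
NORM_EPS = 1e-9


@dataclass(frozen=True)
class PaddleSpec:
    """Geometric description of a regular-grid paddle.

    Pitches are centre-to-centre distances.  For the HD64 the pitches are
    derived from the treatment extents (14.5 mm mediolateral across 5
    columns, 40 mm rostrocaudal across 12 rows); the datasheet-style
    inter-contact gap values (0.7 mm, 0.9 mm) are gaps, not pitches.
    """

    n_rows: int
    n_cols: int
    pitch_ml: float  # mm, centre-to-centre mediolateral
    pitch_rc: float  # mm, centre-to-centre rostrocaudal
    contact_area: float = 4.15  # mm^2
    name: str = "paddle"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_ml <= 0 or self.pitch_rc <= 0:
            raise ValueError("pitches must be positive")


def hd64_spec() -> PaddleSpec:
    """Default 60-contact high-density paddle: 12 rows x 5 columns.

    Pitches place the outer columns 14.5 mm apart (treatment width) and the
    outer rows 40 mm apart (2.5 vertebral segments).
    """
    return PaddleSpec(
        n_rows=12,
        n_cols=5,
        pitch_ml=14.5 / 4,
        pitch_rc=40.0 / 11,
        contact_area=4.15,
        name="hd64",
    )


@dataclass(frozen=True)
class AffineTransform:
    """2D affine map ``p -> A p + b`` with non-singular linear part."""

    linear: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual: float = 0.0  # RMS fit residual, mm

    def __post_init__(self) -> None:
        A = np.asarray(self.linear, dtype=float).reshape(2, 2)
        b = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "linear", A)
        object.__setattr__(self, "offset", b)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.offset

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform(Ainv, -Ainv @ self.offset)


@dataclass(frozen=True)
class PaddleLayout:
    """Per-contact coordinates of a paddle in the paddle frame.

    ``coords_norm`` is populated by :func:`normalize_coords`; components lie
    in ``[0, 1)`` with the left-most caudal contact at ``(0, 0)``.
    """

    electrode_ids: tuple[str, ...]
    coords_mm: np.ndarray  # (n, 2) columns (x=mediolateral, y=rostrocaudal)
    rows: np.ndarray = field(default=None)  # type: ignore[assignment]
    cols: np.ndarray = field(default=None)  # type: ignore[assignment]
    coords_norm: np.ndarray | None = None
    name: str = "paddle"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords_mm, dtype=float).reshape(-1, 2)
        if len(self.electrode_ids) != coords.shape[0]:
            raise ValueError("one coordinate pair per electrode required")
        object.__setattr__(self, "coords_mm", coords)
        if self.coords_norm is not None:
            norm = np.asarray(self.coords_norm, dtype=float).reshape(-1, 2)
            if norm.shape != coords.shape:
                raise ValueError("coords_norm shape mismatch")
            if np.any(norm < 0) or np.any(norm >= 1):
                raise ValueError("normalized coordinates must lie in [0, 1)")
            object.__setattr__(self, "coords_norm", norm)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def transformed(self, transform: AffineTransform) -> "PaddleLayout":
        return replace(self, coords_mm=transform.apply(self.coords_mm), coords_norm=None)


def build_layout(spec: PaddleSpec) -> PaddleLayout:
    """Place ``n_rows * n_cols`` contacts on a regular grid.

    Contacts are ordered row-major starting from the caudal (y = 0) row and
    the left (x = 0) column, so the row/column of contact ``k`` are
    ``divmod(k, n_cols)``.  Ids are ``"E00"``, ``"E01"``, ...
    """
    rows, cols = np.divmod(np.arange(spec.n_rows * spec.n_cols), spec.n_cols)
    coords = np.column_stack([cols * spec.pitch_ml, rows * spec.pitch_rc]).astype(float)
    width = max(2, len(str(spec.n_rows * spec.n_cols - 1)))
    ids = tuple(f"E{k:0{width}d}" for k in range(spec.n_rows * spec.n_cols))
    return PaddleLayout(ids, coords, rows=rows, cols=cols, name=spec.name)


def medtronic_565_layout() -> PaddleLayout:
    """Scale layout of a commercial 16-contact (5-6-5) comparator paddle.

    Three columns of 5, 6 and 5 contacts; 1.0 mm mediolateral and 4.5 mm
    rostrocaudal gaps with 1.5 x 4 mm contacts (6 mm^2), the outer columns
    staggered by half a row pitch.  Used for footprint-overlay comparisons.
    """
    pitch_ml = 1.5 + 1.0
    pitch_rc = 4.0 + 4.5
    ids, coords = [], []
    col_rows = (5, 6, 5)
    for c, n in enumerate(col_rows):
        y0 = 0.0 if n == 6 else pitch_rc / 2
        for r in range(n):
            ids.append(f"M{len(ids):02d}")
            coords.append((c * pitch_ml, y0 + r * pitch_rc))
    return PaddleLayout(tuple(ids), np.array(coords), name="5-6-5")


def fit_affine(observed: np.ndarray, canonical: np.ndarray) -> AffineTransform:
    """Least-squares affine mapping ``canonical -> observed``.

    Solves for the 2x2 linear part and offset minimizing the summed squared
    residuals over >= 3 non-collinear point pairs (e.g. radiograph landmark
    positions vs. the nominal paddle frame, to absorb skew between the
    paddle and the imaging plane).
    """
    obs = np.asarray(observed, dtype=float).reshape(-1, 2)
    can = np.asarray(canonical, dtype=float).reshape(-1, 2)
    if obs.shape != can.shape:
        raise ValueError("point lists must have matching shapes")
    if obs.shape[0] < 3:
        raise ValueError("at least 3 point pairs required")
    centered = can - can.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("degenerate geometry: canonical points are collinear")
    design = np.column_stack([can, np.ones(can.shape[0])])
    sol, _, _, _ = np.linalg.lstsq(design, obs, rcond=None)
    A = sol[:2].T
    b = sol[2]
    resid = obs - (can @ A.T + b)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(A, b, residual=rms)


def normalize_coords(
    layout: PaddleLayout,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> PaddleLayout:
    """Normalize physical coordinates to ``[0, 1)^2``.

    Each axis is mapped as ``(v - min) / (span * (1 + eps))`` so the maximum
    falls strictly below 1.  ``extent`` overrides the per-axis ``(min, max)``
    (e.g. the union extent of two stacked paddles); an axis with a single
    distinct value maps to 0.  Idempotent on already-normalized layouts in
    the sense that renormalizing changes coordinates by at most ``eps``.
    """
    coords = layout.coords_mm
    norm = np.zeros_like(coords)
    for ax in range(2):
        v = coords[:, ax]
        lo, hi = (v.min(), v.max()) if extent is None else extent[ax]
        span = hi - lo
        if span <= 0:
            if np.unique(v).size > 1:
                raise ValueError(f"zero span on axis {ax} with multiple coordinate values")
            norm[:, ax] = 0.0
        else:
            norm[:, ax] = (v - lo) / (span * (1.0 + NORM_EPS))
    if np.any(norm < 0) or np.any(norm >= 1):
        raise ValueError("coordinates fall outside the provided extent")
    return replace(layout, coords_norm=norm)


def overlay_comparator(
    source: PaddleLayout,
    source_labels: dict[str, int],
    comparator: PaddleLayout,
    contact_radius: float,
) -> dict[str, frozenset[int]]:
    """Labels of source contacts within each comparator contact footprint.

    Both layouts must be expressed in a common frame.  Returns, for every
    comparator contact, the set of source labels (e.g. cluster ids) whose
    electrodes lie within ``contact_radius`` mm of the comparator contact
    centre.  Empty sets mark labels a comparator contact cannot reach.
    """
    if contact_radius < 0:
        raise ValueError("contact radius must be non-negative")
    out: dict[str, frozenset[int]] = {}
    for cid, centre in zip(comparator.electrode_ids, comparator.coords_mm):
        d = np.linalg.norm(source.coords_mm - centre, axis=1)
        hit = [source_labels[e] for e, within in zip(source.electrode_ids, d <= contact_radius) if within]
        out[cid] = frozenset(hit)
    return out
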