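"""Categorical land-cover grids and circular-buffer cover extraction.

The landscape is a categorical raster on a projected metric grid (planar
coordinates, no geodesy).  Around each sampling site, land-cover composition
is measured inside concentric circular buffers over a series of radii; the
resulting site x radius x class table of cover proportions
(:class:`CoverProfile`) is the input to scale-of-effect selection.

Conventions
-----------
* Cell membership: a cell belongs to a buffer iff its *center* lies within
  Euclidean distance ``radius`` of the site point (comparison on squared
  distances, so the rule is exact in floating point).  The area bias of this
  rule vanishes as ``cell_size / radius`` goes to 0.
* Radius series: half-open ``[r_min, r_max)`` with a uniform step.  The
  canonical series 150-5000 m by 10 m therefore has 485 entries.
* Edge policy: every disc must lie fully inside the grid extent, otherwise
  :class:`~scaleofeffect.errors.OutOfExtentError` is raised.  Truncated
  buffers would silently bias proportions.
* Class set: ``("forest", "urban", "agriculture", "other")``; ``other`` is
  the complement class so per-buffer proportions always sum to 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, OutOfExtentError, ParseError

#: Canonical, exhaustive land-cover class set.  ``other`` absorbs everything
#: that is neither forest, building cover nor agricultural use (lakes,
#: mountains, ...).
CLASSES: tuple[str, ...] = ("forest", "urban", "agriculture", "other")

#: Anthropisation components analysed against responses (``other`` is the
#: complement and is never used as a predictor).
COMPONENTS: tuple[str, ...] = ("forest", "urban", "agriculture")


@dataclass(frozen=True)
class LandscapeGrid:
    """A rectangular categorical raster of land-cover classes.

    Parameters
    ----------
    values
        2-D integer array of class codes, indices into ``classes``.
        Row 0 is the *northern* edge (the usual raster file order).
    cell_size
        Side length of a square cell in meters, > 0.
    origin
        ``(x, y)`` of the grid's lower-left corner in projected meters.
    classes
        Ordered class names; codes in ``values`` index this tuple.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.size == 0:
            raise InvalidArgumentError("grid values must be a non-empty 2-D array")
        if not np.issubdtype(vals.dtype, np.integer):
            raise InvalidArgumentError("grid values must be integer class codes")
        if self.cell_size <= 0:
            raise InvalidArgumentError(f"cell_size must be > 0, got {self.cell_size}")
        if vals.min() < 0 or vals.max() >= len(self.classes):
            raise InvalidArgumentError(
                f"class codes must lie in [0, {len(self.classes) - 1}], "
                f"found range [{vals.min()}, {vals.max()}]"
            )
        object.__setattr__(self, "values", vals)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> float:
        """East-west extent in meters."""
        return self.ncols * self.cell_size

    @property
    def height(self) -> float:
        """North-south extent in meters."""
        return self.nrows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` in projected meters."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.width, y0 + self.height)

    def class_code(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise InvalidArgumentError(
                f"unknown class {cls!r}; declared classes are {self.classes}"
            ) from None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened ``(x, y)`` coordinates of every cell center.

        Ordering matches ``values.ravel()`` (row-major, row 0 = north).
        """
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        cx, cy = np.meshgrid(xs, ys)
        return cx.ravel(), cy.ravel()

    def class_proportions(self) -> dict[str, float]:
        """Grid-wide cover proportion of each class."""
        counts = np.bincount(self.values.ravel(), minlength=len(self.classes))
        return dict(zip(self.classes, counts / self.values.size))


def make_radius_series(r_min: float, r_max: float, step: float) -> np.ndarray:
    """Uniform buffer-radius series on the half-open interval ``[r_min, r_max)``.

    The default multi-scale design, ``make_radius_series(150, 5000, 10)``,
    yields exactly 485 radii (150, 160, ..., 4990).

    Raises
    ------
    InvalidArgumentError
        If ``r_min <= 0``, ``step <= 0`` or ``r_max <= r_min``.
    """
    if r_min <= 0:
        raise InvalidArgumentError(f"r_min must be > 0, got {r_min}")
    if step <= 0:
        raise InvalidArgumentError(f"step must be > 0, got {step}")
    if r_max <= r_min:
        raise InvalidArgumentError(f"r_max ({r_max}) must exceed r_min ({r_min})")
    n = int(np.ceil((r_max - r_min) / step - 1e-12))
    n = max(n, 1)
    return r_min + step * np.arange(n)


def _check_disc_in_extent(
    grid: LandscapeGrid, center: tuple[float, float], radius: float, label: str
) -> None:
    xmin, ymin, xmax, ymax = grid.extent
    x, y = center
    if x - radius < xmin or x + radius > xmax or y - radius < ymin or y + radius > ymax:
        raise OutOfExtentError(
            f"buffer of radius {radius} m around {label} at ({x}, {y}) extends "
            f"beyond the grid extent {grid.extent}"
        )


def cover_fraction(
    grid: LandscapeGrid,
    center: tuple[float, float],
    radius: float,
    cls: str,
) -> float:
    """Fraction of buffer cells holding class ``cls``.

    The buffer is the set of cells whose centers lie within Euclidean
    distance ``radius`` of ``center``; the returned value is
    ``#{cells of class cls in buffer} / #{cells in buffer}``.

    Raises
    ------
    OutOfExtentError
        If the disc is not fully inside the grid.
    InvalidArgumentError
        If ``cls`` is unknown, ``radius <= 0``, or the disc contains no
        cell center (radius below the grid resolution).
    """
    if radius <= 0:
        raise InvalidArgumentError(f"radius must be > 0, got {radius}")
    code = grid.class_code(cls)
    _check_disc_in_extent(grid, center, radius, "point")
    cx, cy = grid.cell_centers()
    d2 = (cx - center[0]) ** 2 + (cy - center[1]) ** 2
    inside = d2 <= radius * radius
    n_in = int(inside.sum())
    if n_in == 0:
        raise InvalidArgumentError(
            f"buffer of radius {radius} m contains no cell center at "
            f"cell size {grid.cell_size} m"
        )
    return float((grid.values.ravel()[inside] == code).sum()) / n_in


@dataclass(frozen=True)
class CoverProfile:
    """Cover proportions indexed by (site, radius, class).

    Internally a dense ``(n_sites, n_radii, n_classes)`` array; per
    ``(site, radius)`` slice the class proportions sum to 1.
    """

    site_ids: tuple[str, ...]
    radii: np.ndarray
    classes: tuple[str, ...]
    proportions: np.ndarray  # (n_sites, n_radii, n_classes)
    _site_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        expected = (len(self.site_ids), len(self.radii), len(self.classes))
        if props.shape != expected:
            raise InvalidArgumentError(
                f"proportions shape {props.shape} does not match "
                f"(sites, radii, classes) = {expected}"
            )
        object.__setattr__(self, "proportions", props)
        object.__setattr__(
            self, "_site_index", {s: i for i, s in enumerate(self.site_ids)}
        )

    def at(self, site_id: str, radius: float, cls: str) -> float:
        i = self._site_index[site_id]
        j = int(np.flatnonzero(np.isclose(self.radii, radius))[0])
        k = self.classes.index(cls)
        return float(self.proportions[i, j, k])

    def matrix(self, cls: str) -> pd.DataFrame:
        """Site x radius matrix of proportions for one class."""
        k = self.classes.index(cls)
        return pd.DataFrame(
            self.proportions[:, :, k], index=list(self.site_ids), columns=self.radii
        )

    def column(self, cls: str, radius: float) -> pd.Series:
        """Per-site cover of one class at one radius."""
        mat = self.matrix(cls)
        j = np.flatnonzero(np.isclose(self.radii, radius))
        if j.size == 0:
            raise InvalidArgumentError(
                f"radius {radius} m is not in the profile's radius series"
            )
        return mat.iloc[:, int(j[0])]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``site_id, radius_m, class, proportion``."""
        rows = []
        for i, s in enumerate(self.site_ids):
            for j, r in enumerate(self.radii):
                for k, c in enumerate(self.classes):
                    rows.append((s, float(r), c, self.proportions[i, j, k]))
        return pd.DataFrame(rows, columns=["site_id", "radius_m", "class", "proportion"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoverProfile":
        sites = tuple(dict.fromkeys(df["site_id"].astype(str)))
        radii = np.array(sorted(df["radius_m"].unique()), dtype=float)
        classes = tuple(dict.fromkeys(df["class"]))
        pivot = df.set_index(["site_id", "radius_m", "class"])["proportion"]
        props = np.empty((len(sites), len(radii), len(classes)))
        for i, s in enumerate(sites):
            for j, r in enumerate(radii):
                for k, c in enumerate(classes):
                    props[i, j, k] = pivot[(s, r, c)]
        return cls(sites, radii, classes, props)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoverProfile":
        return cls.from_frame(pd.read_csv(path))


def build_cover_profile(
    grid: LandscapeGrid,
    sites: pd.DataFrame,
    radii: Sequence[float] | np.ndarray,
    classes: Sequence[str] | None = None,
) -> CoverProfile:
    """Cover proportions for every (site, radius, class) combination.

    For each site the squared distances of all cell centers are sorted once;
    every radius is then a prefix of that ordering, so the whole radius
    series costs one ``O(N log N)`` sort per site.  Each entry equals what
    :func:`cover_fraction` returns for the same arguments.

    Parameters
    ----------
    sites
        Site table with columns ``site_id, x, y`` (``effort`` ignored here).
    """
    if classes is None:
        classes = grid.classes
    codes = [grid.class_code(c) for c in classes]
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise InvalidArgumentError("radius series is empty")
    r_max = float(radii.max())
    cx, cy = grid.cell_centers()
    flat = grid.values.ravel()

    site_ids = tuple(str(s) for s in sites["site_id"])
    props = np.empty((len(site_ids), radii.size, len(classes)))
    r2_sorted_targets = np.asarray(radii, dtype=float) ** 2
    for i, row in enumerate(sites.itertuples(index=False)):
        _check_disc_in_extent(grid, (row.x, row.y), r_max, f"site {row.site_id!r}")
        d2 = (cx - row.x) ** 2 + (cy - row.y) ** 2
        order = np.argsort(d2, kind="stable")
        d2s = d2[order]
        sorted_codes = flat[order]
        # cumulative count of each requested class along the distance ordering
        cum = np.empty((d2s.size + 1, len(codes)), dtype=np.int64)
        cum[0] = 0
        for k, code in enumerate(codes):
            np.cumsum(sorted_codes == code, out=cum[1:, k])
        ks = np.searchsorted(d2s, r2_sorted_targets, side="right")
        if np.any(ks == 0):
            bad = radii[ks == 0].min()
            raise InvalidArgumentError(
                f"buffer of radius {bad} m around site {row.site_id!r} contains "
                "no cell center"
            )
        props[i] = cum[ks] / ks[:, None]
    return CoverProfile(site_ids, radii, tuple(classes), props)


# ---------------------------------------------------------------------------
# File formats: ESRI ASCII grid (+ class-map sidecar) and site CSV
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _classmap_path(path: str | Path) -> Path:
    return Path(str(path) + ".classes.csv")


def write_grid(grid: LandscapeGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid plus a ``<path>.classes.csv`` sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {grid.origin[1]!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        for row in grid.values:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
    with _classmap_path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "class"])
        for code, name in enumerate(grid.classes):
            writer.writerow([code, name])


def read_grid(path: str | Path) -> LandscapeGrid:
    """Read an ESRI ASCII grid written by :func:`write_grid`.

    The class-map sidecar is optional; without it codes 0..3 map to the
    canonical class set.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}: header line {n_header + 1}: non-numeric value "
                    f"{parts[1]!r} for {parts[0]}"
                ) from None
            n_header += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ParseError(f"{path}: missing header keys {missing}")
    try:
        values = np.array(
            [[int(v) for v in line.split()] for line in lines[n_header:] if line.strip()],
            dtype=np.int64,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer cell value ({exc})") from None
    if values.ndim != 2 or values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    classes = CLASSES
    cmap = _classmap_path(path)
    if cmap.exists():
        with cmap.open() as fh:
            rows = list(csv.DictReader(fh))
        try:
            pairs = sorted((int(r["code"]), r["class"]) for r in rows)
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{cmap}: malformed class map ({exc})") from None
        if [c for c, _ in pairs] != list(range(len(pairs))):
            raise ParseError(f"{cmap}: class codes must be 0..{len(pairs) - 1}")
        classes = tuple(name for _, name in pairs)
    return LandscapeGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        classes=classes,
    )


def validate_sites(df: pd.DataFrame, source: str = "sites") -> pd.DataFrame:
    """Validate a site table (``site_id, x, y, effort``) and coerce dtypes."""
    required = ["site_id", "x", "y", "effort"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing columns {missing}")
    df = df.copy()
    df["site_id"] = df["site_id"].astype(str)
    dup = df["site_id"][df["site_id"].duplicated()].unique()
    if dup.size:
        raise ParseError(f"{source}: duplicate site_id(s) {list(dup)}")
    for col in ("x", "y", "effort"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ParseError(
                f"{source}: non-numeric {col!r} at row {bad}"
            ) from None
    if (df["effort"] < 1).any():
        bad = df.loc[df["effort"] < 1, "site_id"].tolist()
        raise ParseError(f"{source}: effort must be >= 1 (sites {bad})")
    df["effort"] = df["effort"].astype(int)
    return df[required].reset_index(drop=True)


def read_sites(path: str | Path) -> pd.DataFrame:
    """Read and validate a ``site_id,x,y,effort`` CSV."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from None
    return validate_sites(df, source=str(path))


def write_sites(df: pd.DataFrame, path: str | Path) -> None:
    validate_sites(df).to_csv(path, index=False)
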