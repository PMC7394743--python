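"""Pearson functional connectivity and regional (PCC-DLPFC) connections.

The connectivity matrix is the Pearson correlation between every pair of
region time series over the retained (uncensored) volumes.  Regional
connectivity between two sets of regions averages the member time series
within each set first and then correlates the two averages
("average-then-correlate"); averaging pairwise correlations instead is
available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoise import RoiTimeSeriesMatrix

__all__ = [
    "ConnectivityMatrix",
    "RegionSet",
    "ZeroVarianceError",
    "pearson_matrix",
    "regional_connectivity",
    "PCC",
    "DLPFC_LEFT",
    "DLPFC_RIGHT",
    "default_region_sets",
]


class ZeroVarianceError(ValueError):
    """A region (or set average) is constant over the retained volumes."""

    def __init__(self, regions):
        self.regions = list(regions)
        super().__init__(
            f"zero variance over retained volumes for region(s) {self.regions}"
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("diagonal must be exactly 1")
        if np.any(np.abs(self.values) > 1.0):
            raise ValueError("entries must lie in [-1, 1]")
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.region_ids.shape != (n,):
            raise ValueError("region_ids length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def pearson_matrix(series: RoiTimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between all region pairs over retained volumes.

    Requires at least 3 retained volumes.  A region with zero variance over
    the retained volumes makes the correlation undefined and raises
    :class:`ZeroVarianceError`.
    """
    X = series.retained_values()
    if X.shape[1] < 3:
        raise ValueError("need at least 3 retained volumes for correlation")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ZeroVarianceError(series.region_ids[sd == 0])
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc /= np.linalg.norm(Xc, axis=1, keepdims=True)
    R = Xc @ Xc.T
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return ConnectivityMatrix(values=R, region_ids=series.region_ids)


@dataclass(frozen=True)
class RegionSet:
    """Named set of parcellation regions with their MNI centres (for docs)."""

    name: str
    members: tuple[int, ...]
    mni_centers: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in region set {self.name}")
        if any(not (1 <= m <= 264) for m in self.members):
            raise ValueError(f"members of {self.name} must lie in 1..264")


# Default node sets (1-based indices into the 264-region functional
# parcellation) for the posterior cingulate cortex and the left/right
# dorsolateral prefrontal cortex, with their MNI centres.
PCC = RegionSet("PCC", (77, 78, 82),
                ((-11.0, -56.0, 16.0), (-3.0, -49.0, 13.0), (11.0, -54.0, 17.0)))
DLPFC_LEFT = RegionSet("DLPFC_left", (167, 176),
                       ((-42.0, 38.0, 21.0), (-34.0, 55.0, 4.0)))
DLPFC_RIGHT = RegionSet("DLPFC_right", (168, 175),
                        ((38.0, 43.0, 15.0), (40.0, 18.0, 40.0)))


def default_region_sets() -> tuple[RegionSet, RegionSet, RegionSet]:
    """(PCC, DLPFC left, DLPFC right) with the standard member regions."""
    return PCC, DLPFC_LEFT, DLPFC_RIGHT


def extract_sphere_series(img, centers_mm, radius_mm: float,
                          tr_seconds: float) -> RoiTimeSeriesMatrix:
    """Average voxel series within spheres of a 4D image (optional helper).

    ``img`` is a 4D NIfTI image or path; ``centers_mm`` an iterable of MNI
    (x, y, z) coordinates.  No default radius is claimed — supply the one
    your parcellation prescribes.  Requires nilearn.
    """
    from nilearn.maskers import NiftiSpheresMasker  # optional dependency

    centers = [tuple(map(float, c)) for c in centers_mm]
    masker = NiftiSpheresMasker(centers, radius=radius_mm, standardize=False)
    signals = masker.fit_transform(img)  # volumes x spheres
    return RoiTimeSeriesMatrix(values=signals.T, tr_seconds=tr_seconds,
                               region_ids=np.arange(1, len(centers) + 1))


def _member_rows(series: RoiTimeSeriesMatrix, rs: RegionSet) -> np.ndarray:
    lookup = {rid: i for i, rid in enumerate(series.region_ids)}
    missing = [m for m in rs.members if m not in lookup]
    if missing:
        raise KeyError(f"region set {rs.name}: regions {missing} absent from series")
    return np.array([lookup[m] for m in rs.members])


def regional_connectivity(series: RoiTimeSeriesMatrix,
                          set_a: RegionSet,
                          set_b: RegionSet,
                          *,
                          mean_pairwise: bool = False) -> float:
    """Connectivity between two disjoint region sets.

    Default: average the member time series within each set over retained
    volumes, then Pearson-correlate the two averages.  With
    ``mean_pairwise=True``, returns the mean of the pairwise correlations
    instead (sensitivity variant).
    """
    if set(set_a.members) & set(set_b.members):
        raise ValueError(
            f"region sets {set_a.name} and {set_b.name} overlap"
        )
    rows_a = _member_rows(series, set_a)
    rows_b = _member_rows(series, set_b)
    X = series.retained_values()
    if mean_pairwise:
        R = pearson_matrix(series).values
        return float(R[np.ix_(rows_a, rows_b)].mean())
    a = X[rows_a].mean(axis=0)
    b = X[rows_b].mean(axis=0)
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError([set_a.name if a.std() == 0 else set_b.name])
    return float(np.corrcoef(a, b)[0, 1])
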