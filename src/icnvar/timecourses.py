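"""Network time-course extraction by spatial regression of template maps.

Each intrinsic connectivity network (ICN) is represented by a spatial
template map.  For every frame of a 4D resting-state series, the frame and
the template are reshaped to vectors over the brain mask and the slope of a
simple linear regression (with intercept) of frame values on template
values is the network's activity at that frame — the spatial-regression
step of dual regression.  Stacking the per-frame betas along time yields
one time-course per network.

The default regresses one template at a time, i.e. each map is its own
univariate spatial regressor.  Because every per-frame fit includes an
intercept, the effective regressor is the *centered* map, and two
spatially disjoint nonnegative maps are negatively correlated once
centered (where one is positive the other sits below its mean).  The
univariate betas therefore carry bounded cross-talk between sources even
for disjoint templates, and arbitrarily strong mixing for overlapping
ones.  ``extract_all(joint=True)`` fits all maps plus the intercept in a
single multiple regression per frame, which separates the sources
exactly in the noiseless case.  The two modes coincide (to numerical
precision) exactly when the maps are mutually orthogonal *and* each is
orthogonal to the constant, i.e. zero-mean within the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import nibabel as nib

#: Canonical labels for the ten template networks: medial/occipital/lateral
#: visual, default mode, cerebellum, sensorimotor, auditory, executive
#: control, right/left frontoparietal.
DEFAULT_ICN_LABELS = (
    "MVN", "OVN", "LVN", "DMN", "CBN", "SMN", "AN", "ECN", "RFPN", "LFPN",
)


@dataclass
class SpatialTemplateSet:
    """A stack of network template maps over a common voxel grid.

    ``maps`` has shape (n_components, X, Y, Z); ``mask`` is a boolean array
    of shape (X, Y, Z) selecting in-brain voxels.  ``labels`` name the
    components in order.
    """

    maps: np.ndarray
    mask: np.ndarray
    labels: tuple[str, ...] = DEFAULT_ICN_LABELS

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.maps.ndim != 4:
            raise ValueError("maps must have shape (n_components, X, Y, Z)")
        if self.mask.shape != self.maps.shape[1:]:
            raise ValueError("mask grid does not match template grid")
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        self.labels = tuple(self.labels)[: self.n_components]
        if len(self.labels) < self.n_components:
            self.labels = self.labels + tuple(
                f"ICN{i + 1}" for i in range(len(self.labels), self.n_components)
            )

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    def to_nifti(self) -> nib.Nifti1Image:
        """Pack the maps as a 4D NIfTI image (components along the 4th axis)."""
        data = np.moveaxis(self.maps, 0, -1)
        return nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))

    @classmethod
    def from_nifti(cls, img, mask=None, labels=DEFAULT_ICN_LABELS) -> "SpatialTemplateSet":
        if isinstance(img, (str,)) or hasattr(img, "__fspath__"):
            img = nib.load(str(img))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        maps = np.moveaxis(data, -1, 0)
        if mask is None:
            mask = np.ones(maps.shape[1:], dtype=bool)
        return cls(maps=maps, mask=mask, labels=labels)


@dataclass
class TimeSeriesMatrix:
    """T timepoints x N components of network activity (betas per frame)."""

    data: np.ndarray
    tr_seconds: float
    labels: tuple[str, ...] = DEFAULT_ICN_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x N matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("time-course matrix contains non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.labels = tuple(self.labels)[: self.n_components]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


def _as_volume_array(volume4d) -> np.ndarray:
    if isinstance(volume4d, (str,)) or hasattr(volume4d, "__fspath__"):
        volume4d = nib.load(str(volume4d))
    if isinstance(volume4d, nib.spatialimages.SpatialImage):
        volume4d = volume4d.get_fdata()
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4D volume with time along the last axis")
    return vol


def extract_timecourse(volume4d, template_map, mask) -> np.ndarray:
    """Spatially regress one template on each frame; return the beta series.

    For frame t the returned value is the slope of the ordinary
    least-squares fit (with intercept) of the in-mask frame voxels on the
    in-mask template voxels.  The intercept absorbs any global per-frame
    offset, so adding a constant to a frame leaves its beta unchanged.
    """
    vol = _as_volume_array(volume4d)
    template_map = np.asarray(template_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if template_map.shape != vol.shape[:3] or mask.shape != vol.shape[:3]:
        raise ValueError("volume, template and mask must share the voxel grid")
    m = template_map[mask]
    if m.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    mc = m - m.mean()
    denom = float(mc @ mc)
    if denom == 0.0:
        raise ValueError("template is constant within the mask; regression undefined")
    frames = vol[mask, :]                       # (n_voxels, T)
    frames = frames - frames.mean(axis=0)       # per-frame centering == intercept
    return (mc @ frames) / denom


def extract_all(
    volume4d,
    templates: SpatialTemplateSet,
    joint: bool = False,
    tr_seconds: float = 2.0,
) -> TimeSeriesMatrix:
    """Extract one time-course per template; columns follow template order.

    ``joint=False`` regresses each map separately (the literal per-network
    recipe); ``joint=True`` fits all maps plus an intercept in one multiple
    regression per frame, which separates overlapping templates.
    """
    if templates.n_components == 0:
        raise ValueError("template set is empty")
    vol = _as_volume_array(volume4d)
    if templates.grid_shape != vol.shape[:3]:
        raise ValueError("volume grid does not match template grid")
    if joint:
        mask = templates.mask
        M = templates.maps[:, mask].T                   # (n_voxels, N)
        design = np.column_stack([np.ones(M.shape[0]), M])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("templates are collinear within the mask; joint fit undefined")
        betas, *_ = np.linalg.lstsq(design, vol[mask, :], rcond=None)
        data = betas[1:, :].T
    else:
        cols = []
        for i in range(templates.n_components):
            try:
                cols.append(extract_timecourse(vol, templates.maps[i], templates.mask))
            except ValueError as err:
                raise ValueError(f"component {templates.labels[i]}: {err}") from err
        data = np.column_stack(cols)
    return TimeSeriesMatrix(data=data, tr_seconds=tr_seconds, labels=templates.labels)


def save_timecourses_tsv(tc: TimeSeriesMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(tc.data, columns=list(tc.labels)).to_csv(path, sep="\t", index=False)


def load_timecourses_tsv(path, tr_seconds: float) -> TimeSeriesMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(df.to_numpy(float), tr_seconds, tuple(df.columns))
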