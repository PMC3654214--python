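"""Reduce 4-D functional volumes to regional mean time series via a label atlas.

Each region of an integer-labelled atlas volume (e.g. the 116-region AAL
parcellation) is averaged over its voxels at every timepoint.  Volumes
are read in their native orientation and the functional and label grids
must match voxel-for-voxel: resampling belongs to preprocessing, which
is outside this pipeline.
"""

from __future__ import annotations

import numpy as np

from .connectivity import RegionalTimeSeries


def parcellate(
    functional,
    labels,
    sampling_interval: float | None = None,
    region_names: dict | None = None,
) -> RegionalTimeSeries:
    """Average a 4-D functional image over atlas labels.

    Parameters
    ----------
    functional
        A nibabel spatial image or a (x, y, z, t) array.
    labels
        A nibabel image or (x, y, z) integer array; voxels labelled 0 are
        background.  Regions are ordered by ascending label.
    sampling_interval
        TR in seconds; taken from the NIfTI header (4th zoom) when the
        functional input is an image and the argument is omitted.
    region_names
        Optional label -> name mapping for the output row labels.
    """
    func = np.asanyarray(functional.dataobj) if hasattr(functional, "dataobj") else np.asarray(functional)
    if hasattr(functional, "header") and sampling_interval is None:
        zooms = functional.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            sampling_interval = float(zooms[3])
    if sampling_interval is None:
        raise ValueError("sampling_interval not given and not present in the header")
    lab = np.asanyarray(labels.dataobj) if hasattr(labels, "dataobj") else np.asarray(labels)
    lab = np.rint(lab).astype(int)
    if func.ndim != 4:
        raise ValueError("functional input must be 4-D (x, y, z, t)")
    if lab.shape != func.shape[:3]:
        raise ValueError(
            f"label grid {lab.shape} does not match functional grid {func.shape[:3]}"
        )
    if np.any(lab < 0):
        raise ValueError("labels must be non-negative integers")
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no positive labels in the atlas volume")
    t = func.shape[3]
    flat = func.reshape(-1, t)
    lab_flat = lab.ravel()
    series = np.empty((ids.size, t))
    for row, r in enumerate(ids):
        mask = lab_flat == r
        series[row] = flat[mask].mean(axis=0)
    names = tuple(
        str(region_names.get(int(r), f"region-{int(r)}")) if region_names else f"region-{int(r)}"
        for r in ids
    )
    return RegionalTimeSeries(series, names, sampling_interval)
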