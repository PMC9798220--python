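"""Frequency variability of brain regions across band-specific networks.

For node i with connectivity profile FC_{f,i} in band f (its column of
the band-f network with the self-connection removed), frequency
variability is one minus the mean Pearson correlation over unordered
band pairs:

    FV_i = 1 - mean_{f<g} corr(FC_{f,i}, FC_{g,i})

FV_i = 0 when a region's connectivity profile is identical across
bands and reaches 2 when the profiles are perfectly anti-correlated;
higher values mean the region's connectivity differs more between
frequency bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .connectivity import _as_array

__all__ = ["FvVector", "frequency_variability"]


@dataclass
class FvVector:
    values: np.ndarray
    n_bands: int
    band_labels: list[str] = field(default_factory=list)
    undefined_rois: list[int] = field(default_factory=list)


def frequency_variability(networks: list, band_labels: list[str] | None = None
                          ) -> FvVector:
    """Per-ROI frequency variability across two or more band networks.

    ROIs whose connectivity profile has zero variance in any band have
    an undefined correlation; their FV is NaN and they are reported in
    ``undefined_rois``.
    """
    mats = [_as_array(w) for w in networks]
    if len(mats) < 2:
        raise ValueError("need at least two band networks")
    P = mats[0].shape[0]
    if any(m.shape != (P, P) for m in mats):
        raise ValueError("all band networks must share the same P")

    fv = np.zeros(P)
    undefined: list[int] = []
    keep = ~np.eye(P, dtype=bool)
    for i in range(P):
        profiles = [m[:, i][keep[:, i]] for m in mats]
        if any(np.std(p) == 0 for p in profiles):
            fv[i] = np.nan
            undefined.append(i)
            continue
        corrs = [np.corrcoef(profiles[f], profiles[g])[0, 1]
                 for f, g in combinations(range(len(mats)), 2)]
        fv[i] = 1.0 - float(np.mean(corrs))
    return FvVector(values=fv, n_bands=len(mats),
                    band_labels=list(band_labels or []),
                    undefined_rois=undefined)
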