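"""Synthetic resting-state cohorts with band-limited latent structure.

Each ROI signal is the sum of a low-frequency component, a
high-frequency component and white measurement noise.  Within each band
the components follow a community factor model: ROIs in the same
community share a band-limited community latent, so their band-filtered
signals correlate at a controlled baseline level.  A group difference is
planted by giving patient subjects extra shared "pair" latents on
selected edges in one band (or split across both), shifting those edges'
target correlation by a known amount while keeping every signal at unit
variance — the effect changes mixing weights, not signal power.

Ground-truth per-band, per-group correlation matrices are returned
alongside the signals, so every downstream stage (decomposition, network
construction, fusion, classification) can be validated without real
imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import CohortManifest, RoiTimeSeries, write_manifest, write_matrix, \
    write_roi_timeseries

__all__ = ["CohortSpec", "SyntheticCohort", "generate_band_limited_latent",
           "generate_cohort", "write_cohort", "null_cohort_spec"]

#: default frequency bands (Hz): slow fluctuations vs the faster band
#: that the first intrinsic mode captures
LOW_BAND = (0.015, 0.06)
HIGH_BAND = (0.06, 0.15)


def _default_communities(P: int, offset: int = 0) -> list[list[int]]:
    half = P // 2
    rois = list(range(P))
    rois = rois[offset:] + rois[:offset]
    return [sorted(rois[:half]), sorted(rois[half:])]


@dataclass
class CohortSpec:
    """Parameters of one synthetic two-group cohort.

    ``effect_band`` may be ``'low'``, ``'high'`` or ``'both'``; with
    ``'both'`` the sorted effect edges alternate between the two bands,
    planting complementary group differences.  ``effect_size`` is the
    correlation shift on effect edges for the patient group and must
    satisfy ``within_corr + effect_size <= 1`` for within-community
    edges.
    """

    n_per_group: int = 30
    P: int = 20
    T: int = 137
    TR: float = 3.0
    low_band: tuple = LOW_BAND
    high_band: tuple = HIGH_BAND
    communities_low: list = None
    communities_high: list = None
    effect_edges: list = field(default_factory=list)
    effect_band: str = "high"
    effect_size: float = 0.0
    within_corr: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        nyquist = 1.0 / (2.0 * self.TR)
        for band in (self.low_band, self.high_band):
            if not 0 < band[0] < band[1] <= nyquist:
                raise ValueError(
                    f"band {band} outside (0, Nyquist={nyquist:.4g}]")
        if self.low_band[1] > self.high_band[0]:
            raise ValueError("low band must end at or below the high band")
        if self.communities_low is None:
            self.communities_low = _default_communities(self.P)
        if self.communities_high is None:
            self.communities_high = _default_communities(self.P, self.P // 4)
        for comms in (self.communities_low, self.communities_high):
            if any(len(c) == 0 for c in comms):
                raise ValueError("empty community")
            members = sorted(i for c in comms for i in c)
            if members != list(range(self.P)):
                raise ValueError("communities must partition the ROIs")
        if self.effect_band not in ("low", "high", "both"):
            raise ValueError("effect_band must be 'low', 'high' or 'both'")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must be in [0, 1]")
        self.effect_edges = sorted(tuple(e) for e in self.effect_edges)
        for i, j in self.effect_edges:
            if not 0 <= i < j < self.P:
                raise ValueError(f"effect edge ({i},{j}) not in upper triangle")

    def edges_by_band(self) -> dict[str, list[tuple[int, int]]]:
        if self.effect_band == "both":
            return {"low": self.effect_edges[0::2],
                    "high": self.effect_edges[1::2]}
        other = "high" if self.effect_band == "low" else "low"
        return {self.effect_band: list(self.effect_edges), other: []}


@dataclass
class SyntheticCohort:
    subjects: list[RoiTimeSeries]
    truth_low: dict        # group label -> P x P target correlation matrix
    truth_high: dict
    spec: CohortSpec = None


def generate_band_limited_latent(T: int, TR: float, band, seed) -> np.ndarray:
    """Unit-variance series with spectral mass confined to ``band``.

    White noise is masked in the Fourier domain (only rFFT bins with
    frequency inside the band survive) and standardised, giving an
    exactly controllable spectrum with >= 90% of periodogram mass inside
    the band.
    """
    nyquist = 1.0 / (2.0 * TR)
    if not 0 < band[0] < band[1] <= nyquist:
        raise ValueError(f"band {band} outside (0, Nyquist={nyquist:.4g}]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    white = rng.standard_normal(T)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(T, d=TR)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bin at T={T}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=T)
    return (x - x.mean()) / x.std()


def _loading_matrix(spec: CohortSpec, band: str, with_effect: bool
                    ) -> np.ndarray:
    """Rows = ROIs, columns = latent factors; cov of signals = L L^T.

    Factor order: community latents, pair latents (patient group only),
    then one unique latent per ROI.  Row norms are 1, so each ROI's
    band component has unit variance and L L^T has a unit diagonal.
    """
    comms = spec.communities_low if band == "low" else spec.communities_high
    edges = spec.edges_by_band()[band] if with_effect else []
    n_factors = len(comms) + len(edges) + spec.P
    L = np.zeros((spec.P, n_factors))
    w = np.sqrt(spec.within_corr)
    for c, members in enumerate(comms):
        for i in members:
            L[i, c] = w
    e_load = np.sqrt(spec.effect_size)
    for e, (i, j) in enumerate(edges):
        L[i, len(comms) + e] = e_load
        L[j, len(comms) + e] = e_load
    for i in range(spec.P):
        shared = float(np.sum(L[i] ** 2))
        if shared > 1.0 + 1e-12:
            raise ValueError(
                f"ROI {i}: shared loadings exceed unit variance in band "
                f"{band}; reduce within_corr or effect_size")
        L[i, len(comms) + len(edges) + i] = np.sqrt(max(0.0, 1.0 - shared))
    return L


def _band_component(L: np.ndarray, T: int, TR: float, band,
                    rng: np.random.Generator) -> np.ndarray:
    latents = np.stack([
        generate_band_limited_latent(T, TR, band, rng)
        for _ in range(L.shape[1])
    ])
    return L @ latents


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a seeded two-group cohort with known per-band structure.

    Group labels: 0 = control (baseline networks), 1 = patient (effect
    edges shifted by ``effect_size`` in the configured band(s)).
    """
    rng = np.random.default_rng(spec.seed)
    loadings = {
        ("low", 0): _loading_matrix(spec, "low", with_effect=False),
        ("low", 1): _loading_matrix(spec, "low", with_effect=True),
        ("high", 0): _loading_matrix(spec, "high", with_effect=False),
        ("high", 1): _loading_matrix(spec, "high", with_effect=True),
    }
    truth = {(band, grp): L @ L.T for (band, grp), L in loadings.items()}

    subjects = []
    for grp in (0, 1):
        for s in range(spec.n_per_group):
            low = _band_component(loadings[("low", grp)], spec.T, spec.TR,
                                  spec.low_band, rng)
            high = _band_component(loadings[("high", grp)], spec.T, spec.TR,
                                   spec.high_band, rng)
            X = low + high + spec.noise_sd * rng.standard_normal(
                (spec.P, spec.T))
            subjects.append(RoiTimeSeries(
                values=X, subject_id=f"g{grp + 1}_s{s:03d}", label=grp,
                TR=spec.TR))
    return SyntheticCohort(
        subjects=subjects,
        truth_low={0: truth[("low", 0)], 1: truth[("low", 1)]},
        truth_high={0: truth[("high", 0)], 1: truth[("high", 1)]},
        spec=spec)


def null_cohort_spec(P: int = 64, n_per_group: int = 30, seed: int = 0,
                     **kwargs) -> CohortSpec:
    """Cohort with no group effect and one ROI per community.

    With singleton communities every ROI signal is independent, so the
    P(P-1)/2 edge features are (nearly) independent null variables —
    the right reference for selection-calibration checks.
    """
    singletons = [[i] for i in range(P)]
    return CohortSpec(P=P, n_per_group=n_per_group, effect_size=0.0,
                      communities_low=singletons,
                      communities_high=[list(c) for c in singletons],
                      seed=seed, **kwargs)


def write_cohort(cohort: SyntheticCohort, outdir) -> CohortManifest:
    """Write one TSV per subject, truth matrices, manifest and spec.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for ts in cohort.subjects:
        fname = f"{ts.subject_id}.tsv"
        write_roi_timeseries(ts, outdir / fname)
        records.append({"subject_id": ts.subject_id, "label": ts.label,
                        "path": fname})
    for band, truths in (("low", cohort.truth_low),
                         ("high", cohort.truth_high)):
        for grp, name in ((0, "g1"), (1, "g2")):
            write_matrix(truths[grp], outdir / f"truth_{band}_{name}.tsv")
    spec = cohort.spec
    manifest = CohortManifest(records=records, P=spec.P, T=spec.T, TR=spec.TR)
    write_manifest(manifest, outdir / "manifest.tsv")
    spec_dict = {
        "n_per_group": spec.n_per_group, "P": spec.P, "T": spec.T,
        "TR": spec.TR, "low_band": list(spec.low_band),
        "high_band": list(spec.high_band),
        "communities_low": [list(c) for c in spec.communities_low],
        "communities_high": [list(c) for c in spec.communities_high],
        "effect_edges": [list(e) for e in spec.effect_edges],
        "effect_band": spec.effect_band, "effect_size": spec.effect_size,
        "within_corr": spec.within_corr, "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    with open(outdir / "spec.yaml", "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=False)
    return manifest
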