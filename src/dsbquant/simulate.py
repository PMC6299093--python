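"""Synthetic data generators for every pipeline stage.

The simulators emit exactly the objects (and on-disk dialects) the analysis
stages read, so the whole package is exercisable without any external
download:

* :func:`simulate_smlm_nucleus` — two-channel clustered point patterns
  inside a nucleus ROI.  Channel-A cluster centroids are uniform over the
  ROI (restricted so each cluster's disc fits wholly inside); a fraction
  ``f`` of channel-B clusters is seeded at randomly chosen A centroids with
  Gaussian placement jitter, the rest uniform; member localizations are
  Gaussian around each centroid, truncated at the drawn cluster radius;
  uniform background localizations are appended per channel.  Ground truth
  records which B clusters are colocalized.
* :func:`simulate_drip_experiment` — negative-binomial bin counts for a cut
  and an uncut condition, with the cut mean scaled by a piecewise-linear
  fold-enrichment profile of absolute distance from the nearest cut site
  (default: 1 at the break, peaking at 1.5 kb, back to 1 by 3 kb).
* :func:`simulate_qpcr_table` — replicated IP/input quantities with
  log-normal multiplicative measurement noise of stated CV.

All simulators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .smlm import MaskROI, NucleusROI, PolygonROI, roi_from_polygon
from . import coloc as _coloc

__all__ = [
    "SmlmSimSpec",
    "DripSimSpec",
    "SimulatedNucleus",
    "simulate_smlm_nucleus",
    "truth_cluster_sets",
    "simulate_drip_experiment",
    "scramble_sites",
    "simulate_qpcr_table",
    "amplitude_profile",
]


def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


# ---------------------------------------------------------------------------
# SMLM point patterns
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SmlmSimSpec:
    """Study conditions for one simulated nucleus.

    Defaults reproduce the reference imaging geometry used throughout the
    colocalization analyses: a 10 x 10 um nuclear ROI with 40 clusters per
    channel of 100-nm radius, ~30 localizations per cluster, no background,
    and independent channels (``coloc_fraction = 0``).
    """

    roi_width_nm: float = 10_000.0
    roi_height_nm: float = 10_000.0
    roi_mask: np.ndarray | None = None  # optional binary mask ROI
    roi_mask_pixel_nm: float = 100.0
    n_clusters_a: int = 40
    n_clusters_b: int = 40
    coloc_fraction: float = 0.0
    jitter_sigma_nm: float = 50.0
    radius_mean_nm: float = 100.0
    radius_sd_nm: float = 0.0
    locs_per_cluster: float = 30.0
    background_per_um2_a: float = 0.0
    background_per_um2_b: float = 0.0
    channel_a: str = "gH2AX"
    channel_b: str = "S9.6"

    def __post_init__(self):
        if not 0 <= self.coloc_fraction <= 1:
            raise ParameterError("coloc_fraction must be in [0, 1]")
        if min(self.background_per_um2_a, self.background_per_um2_b) < 0:
            raise ParameterError("background densities must be >= 0")


@dataclasses.dataclass
class SimulatedNucleus:
    nucleus_id: str
    table: pd.DataFrame  # canonical localization table, both channels
    roi: NucleusROI
    truth: pd.DataFrame  # channel, x, y, radius, n_localizations, colocalized


def _draw_radii(spec: SmlmSimSpec, n: int, rng) -> np.ndarray:
    if spec.radius_sd_nm <= 0:
        return np.full(n, float(spec.radius_mean_nm))
    r = rng.normal(spec.radius_mean_nm, spec.radius_sd_nm, n)
    return np.clip(r, 0.1 * spec.radius_mean_nm, None)


def _member_offsets(radius: float, n: int, rng) -> np.ndarray:
    """Gaussian offsets (sigma = radius/2) truncated at the cluster radius."""
    off = rng.normal(0.0, radius / 2.0, (n, 2))
    norm = np.hypot(off[:, 0], off[:, 1])
    over = norm > radius
    if over.any():
        off[over] *= (radius / norm[over])[:, None]
    return off


def simulate_smlm_nucleus(
    spec: SmlmSimSpec = SmlmSimSpec(),
    *,
    nucleus_id: str = "sim0",
    rng: np.random.Generator | int | None = None,
) -> SimulatedNucleus:
    """Generate one two-channel nucleus with known colocalization structure.

    Each B cluster is independently colocalized with probability
    ``coloc_fraction``: its centroid is a randomly chosen A centroid plus
    isotropic Gaussian jitter (clamped so its disc stays inside the ROI).
    Raises :class:`~dsbquant.errors.PlacementError` via the ROI when a
    cluster radius exceeds the ROI inradius (infeasible spec).
    """
    rng = _as_rng(rng)
    if spec.roi_mask is not None:
        roi: NucleusROI = MaskROI(spec.roi_mask, spec.roi_mask_pixel_nm, nucleus_id=nucleus_id)
    else:
        w, h = spec.roi_width_nm, spec.roi_height_nm
        roi = roi_from_polygon([(0, 0), (w, 0), (w, h), (0, h)], nucleus_id=nucleus_id)

    radii_a = _draw_radii(spec, spec.n_clusters_a, rng)
    radii_b = _draw_radii(spec, spec.n_clusters_b, rng)
    cent_a = np.vstack(
        [roi.sample_admissible(r, 1, rng)[0] for r in radii_a]
    ) if spec.n_clusters_a else np.empty((0, 2))

    colocalized = rng.random(spec.n_clusters_b) < spec.coloc_fraction
    if spec.n_clusters_a == 0:
        colocalized[:] = False
    cent_b = np.empty((spec.n_clusters_b, 2))
    for j in range(spec.n_clusters_b):
        if colocalized[j]:
            anchor = cent_a[rng.integers(0, spec.n_clusters_a)]
            pos = anchor + rng.normal(0.0, spec.jitter_sigma_nm, 2)
            xmin, ymin, xmax, ymax = roi.bounds
            r = radii_b[j]
            pos = np.clip(pos, [xmin + r, ymin + r], [xmax - r, ymax - r])
            cent_b[j] = pos
        else:
            cent_b[j] = roi.sample_admissible(radii_b[j], 1, rng)[0]

    frames = {"next": 0}

    def _emit(channel, centroids, radii, coloc_flags):
        loc_rows, truth_rows = [], []
        for i in range(len(centroids)):
            n = max(1, int(rng.poisson(spec.locs_per_cluster)))
            pts = centroids[i] + _member_offsets(radii[i], n, rng)
            pts = np.clip(pts, [0, 0], [roi.bounds[2], roi.bounds[3]])
            loc_rows.append(pts)
            truth_rows.append(
                {
                    "channel": channel,
                    "x": centroids[i][0],
                    "y": centroids[i][1],
                    "radius": radii[i],
                    "n_localizations": n,
                    "colocalized": bool(coloc_flags[i]),
                }
            )
        area_um2 = roi.area / 1e6
        dens = spec.background_per_um2_a if channel == spec.channel_a else spec.background_per_um2_b
        n_bg = int(rng.poisson(dens * area_um2)) if dens > 0 else 0
        if n_bg:
            bg = _uniform_in_roi(roi, n_bg, rng)
            loc_rows.append(bg)
        pts = np.vstack(loc_rows) if loc_rows else np.empty((0, 2))
        f0 = frames["next"]
        frames["next"] += len(pts)
        tbl = pd.DataFrame(
            {
                "nucleus_id": nucleus_id,
                "channel": channel,
                "x": pts[:, 0],
                "y": pts[:, 1],
                "frame": np.arange(f0, f0 + len(pts)),
            }
        )
        return tbl, pd.DataFrame(truth_rows)

    tbl_a, truth_a = _emit(spec.channel_a, cent_a, radii_a, np.zeros(len(cent_a), bool))
    tbl_b, truth_b = _emit(spec.channel_b, cent_b, radii_b, colocalized)
    table = pd.concat([tbl_a, tbl_b], ignore_index=True)
    truth = pd.concat([truth_a, truth_b], ignore_index=True)
    return SimulatedNucleus(nucleus_id=nucleus_id, table=table, roi=roi, truth=truth)


def _uniform_in_roi(roi: NucleusROI, n: int, rng) -> np.ndarray:
    xmin, ymin, xmax, ymax = roi.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 32)
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        keep = roi.contains(cand[:, 0], cand[:, 1])
        acc = cand[keep]
        take = min(len(acc), n - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
    return out


def truth_cluster_sets(sim: SimulatedNucleus, spec: SmlmSimSpec = SmlmSimSpec()):
    """Ground-truth ClusterSets (nominal centroids and radii, no detection).

    Useful for exercising the overlap statistic at the cluster level, where
    the randomization null is defined, independently of cluster detection.
    """
    sets = []
    for channel in (spec.channel_a, spec.channel_b):
        sub = sim.truth[sim.truth["channel"] == channel]
        clusters = [
            _coloc.Cluster(
                cluster_id=i,
                channel=channel,
                centroid=(float(r.x), float(r.y)),
                radius=float(r.radius),
                n_localizations=int(r.n_localizations),
                member_offsets=np.empty((0, 2)),
            )
            for i, r in enumerate(sub.itertuples(index=False))
        ]
        sets.append(
            _coloc.ClusterSet(nucleus_id=sim.nucleus_id, channel=channel, clusters=clusters)
        )
    return tuple(sets)


# ---------------------------------------------------------------------------
# DRIP-style binned counts around cut sites
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DripSimSpec:
    """Study conditions for a simulated cut/uncut binned coverage experiment.

    The fold-enrichment profile ``a(d)`` of absolute distance ``d`` from the
    break is piecewise linear: 1 at ``d = 0``, rising to ``peak_fold`` at
    ``peak_distance`` (default 1.5 kb) and declining back to 1 by
    ``profile_end`` (default 3 kb); 1 outside.  Counts are negative binomial
    with variance ``m + m^2 / dispersion`` (``dispersion = inf`` gives the
    Poisson limit); the default dispersion of 50 emulates the mild technical
    overdispersion between two sequencing libraries of the same sample pool,
    not biological-replicate variability.  The default 100-Mb chromosome
    keeps the enriched footprints a negligible fraction of the library, as
    they are in a real genome, so total-count normalization is undistorted.
    """

    chrom: str = "chr1"
    chrom_length: int = 100_000_000
    n_sites: int = 50
    frac_genic: float = 0.5
    peak_fold: float = 3.0
    peak_distance: int = 1500
    profile_end: int = 3000
    baseline_mean: float = 100.0
    nb_dispersion: float = 50.0
    bin_width: int = 50
    library_factor_cut: float = 1.0
    library_factor_uncut: float = 1.0
    min_site_separation: int = 5000  # 2 x 2.5 kb: keeps window footprints disjoint

    def __post_init__(self):
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ParameterError("dispersion must be > 0")
        if self.peak_fold < 1:
            raise ParameterError("peak_fold must be >= 1 (no depletion profiles)")


def amplitude_profile(d: np.ndarray, spec: DripSimSpec) -> np.ndarray:
    """Fold enrichment as a function of absolute distance from the break."""
    d = np.abs(np.asarray(d, float))
    up = 1.0 + (spec.peak_fold - 1.0) * (d / spec.peak_distance)
    down = 1.0 + (spec.peak_fold - 1.0) * (
        (spec.profile_end - d) / (spec.profile_end - spec.peak_distance)
    )
    a = np.where(d <= spec.peak_distance, up, down)
    return np.where(d >= spec.profile_end, 1.0, a)


def _place_sites(spec: DripSimSpec, rng, *, forbidden: np.ndarray | None = None,
                 max_attempts: int = 10_000) -> np.ndarray:
    lo, hi = spec.profile_end, spec.chrom_length - spec.profile_end
    if hi <= lo:
        raise ParameterError("chromosome too short for the requested profile")
    placed: list[int] = []
    attempts = 0
    while len(placed) < spec.n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise ParameterError(
                "could not place sites with the requested separation; "
                "chromosome too short or too many sites"
            )
        cand = int(rng.integers(lo, hi))
        if placed and np.min(np.abs(np.array(placed) - cand)) < spec.min_site_separation:
            continue
        if forbidden is not None and np.min(np.abs(forbidden - cand)) < spec.profile_end:
            continue
        placed.append(cand)
    return np.array(sorted(placed))


def _nb_counts(mean: np.ndarray, dispersion: float | None, rng) -> np.ndarray:
    mean = np.clip(np.asarray(mean, float), 1e-9, None)
    if dispersion is None or not math.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_drip_experiment(
    spec: DripSimSpec = DripSimSpec(),
    *,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Simulate cut/uncut count tracks, a cut-site table and ground truth.

    Returns a dict with ``cut`` and ``uncut`` :class:`~dsbquant.enrichment.BinTrack`
    count tracks, the ``sites`` table (distinct cleavage scores, Bernoulli
    genic flags) and per-bin ``truth`` (amplitude and expected log2 ratio).
    """
    from .enrichment import BinTrack

    rng = _as_rng(rng)
    positions = _place_sites(spec, rng)
    n_bins = spec.chrom_length // spec.bin_width
    starts = np.arange(n_bins, dtype=np.int64) * spec.bin_width
    ends = starts + spec.bin_width
    centers = (starts + ends) / 2.0

    idx = np.searchsorted(positions, centers)
    left = positions[np.clip(idx - 1, 0, len(positions) - 1)]
    right = positions[np.clip(idx, 0, len(positions) - 1)]
    d_nearest = np.minimum(np.abs(centers - left), np.abs(centers - right))
    amp = amplitude_profile(d_nearest, spec)

    mean_uncut = spec.baseline_mean * spec.library_factor_uncut * np.ones(n_bins)
    mean_cut = spec.baseline_mean * spec.library_factor_cut * amp
    uncut_counts = _nb_counts(mean_uncut, spec.nb_dispersion, rng)
    cut_counts = _nb_counts(mean_cut, spec.nb_dispersion, rng)

    def _track(values):
        return BinTrack(
            pd.DataFrame(
                {"chrom": spec.chrom, "start": starts, "end": ends, "value": values}
            ),
            spec.bin_width,
        )

    scores = rng.permutation(np.linspace(1.0, 100.0, spec.n_sites))
    genic = rng.random(spec.n_sites) < spec.frac_genic
    sites = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "position": positions,
            "cleavage_score": scores,
            "genic": genic,
            "site_id": [f"site{i}" for i in range(spec.n_sites)],
        }
    )
    truth = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": starts,
            "end": ends,
            "amplitude": amp,
            "expected_log2": np.log2(amp),
        }
    )
    return {"cut": _track(cut_counts), "uncut": _track(uncut_counts),
            "sites": sites, "truth": truth}


def scramble_sites(
    sites: pd.DataFrame,
    spec: DripSimSpec,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Control site table: same scores/flags at positions away from any
    true site's enrichment footprint (matched random undamaged regions)."""
    rng = _as_rng(rng)
    ctrl_spec = dataclasses.replace(spec, n_sites=len(sites))
    positions = _place_sites(
        ctrl_spec, rng, forbidden=sites["position"].to_numpy(np.int64)
    )
    out = sites.copy().reset_index(drop=True)
    out["position"] = positions
    out["site_id"] = [f"ctrl{i}" for i in range(len(out))]
    return out


# ---------------------------------------------------------------------------
# qPCR replicate tables
# ---------------------------------------------------------------------------


def simulate_qpcr_table(
    true_folds: Mapping[str, float],
    cv: float = 0.2,
    n_replicates: int = 6,
    *,
    rng: np.random.Generator | int | None = None,
    uncut_percent_input: float = 0.5,
    input_fraction: float = 0.01,
) -> pd.DataFrame:
    """Replicated IP/input quantities realizing known fold inductions.

    Each replicate measures IP and input for both conditions; the IP
    measurements carry independent mean-one log-normal noise with the given
    coefficient of variation (``cv = 0`` gives exact recovery), while input
    measurements — abundant and precisely quantified — are noise-free.
    Quantities are on an arbitrary common linear scale.
    """
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    rng = _as_rng(rng)
    sigma2 = math.log1p(cv**2)
    sigma = math.sqrt(sigma2)

    def _noise(n):
        if cv == 0:
            return np.ones(n)
        return np.exp(rng.normal(-sigma2 / 2.0, sigma, n))

    rows = []
    for region, fold in true_folds.items():
        pi = {"uncut": uncut_percent_input, "cut": uncut_percent_input * fold}
        for condition in ("uncut", "cut"):
            ip_true = pi[condition] / 100.0  # total chromatin = 1 unit
            noise = _noise(n_replicates)
            for rep in range(n_replicates):
                rows.append(
                    {"region": region, "condition": condition, "fraction": "IP",
                     "replicate": rep, "quantity": ip_true * noise[rep]}
                )
                rows.append(
                    {"region": region, "condition": condition, "fraction": "input",
                     "replicate": rep, "quantity": input_fraction}
                )
    return pd.DataFrame(rows)
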