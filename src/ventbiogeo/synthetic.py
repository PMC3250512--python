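"""Province-structured synthetic metacommunities and two-taxon alignments.

Stands in for external occurrence datasets so every pipeline stage can be
exercised offline: per-province endemic species pools with a tunable
endemicity, a shared cosmopolitan fraction, per-site detection effort, and
geographically clustered coordinates.  Alignment pairs are simulated under
the TN93 substitution process at a requested expected distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .community import CommunityMatrix, SiteRecord
from .divergence import AlignedSeqSet

__all__ = [
    "MetacommunityParams",
    "SyntheticMetacommunity",
    "generate_metacommunity",
    "generate_pair_alignment",
]


@dataclass
class MetacommunityParams:
    n_provinces: int = 3
    sites_per_province: int = 10
    endemics_per_province: int = 15
    cosmopolitan_species: int = 5
    endemicity: float = 0.9
    detection_prob: float = 0.9
    coordinate_spread_deg: float = 2.0
    # province centroids default to an equally spaced longitudinal band;
    # straddle_dateline shifts the band so one province crosses +-180
    straddle_dateline: bool = False

    def validate(self) -> None:
        if self.n_provinces < 1:
            raise ValueError("need at least one province")
        if self.n_provinces * self.sites_per_province < 2:
            raise ValueError("need at least two sites in total")
        if not 0.0 <= self.endemicity <= 1.0:
            raise ValueError("endemicity must be in [0, 1]")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in (0, 1]")


@dataclass
class SyntheticMetacommunity:
    matrix: CommunityMatrix
    true_labels: dict[str, int]
    sites: list[SiteRecord]
    params: MetacommunityParams
    seed: int
    province_centroids: list[tuple[float, float]] = field(default_factory=list)


def _province_centroids(params: MetacommunityParams) -> list[tuple[float, float]]:
    K = params.n_provinces
    # spread provinces along longitude, alternating latitude bands
    if params.straddle_dateline:
        # last province sits on +-180; the others stay clear of every
        # scheme's cut line (0, -60, +-180)
        lons = [-135.0 + 90.0 * k for k in range(K - 1)] + [179.0]
    else:
        lons = [-150.0 + 300.0 * (k + 0.5) / K for k in range(K)]
    lats = [20.0 * (-1) ** k for k in range(K)]
    return list(zip(lats, lons))


def generate_metacommunity(
    params: MetacommunityParams | None = None, seed: int = 0
) -> SyntheticMetacommunity:
    """Draw a binary site x species matrix with known province structure.

    A site carries each endemic of its own province with probability
    ``endemicity * detection_prob``, endemics of other provinces with
    probability ``(1 - endemicity) * detection_prob``, and every
    cosmopolitan species with probability ``detection_prob``.  Sites are
    jittered around their province centroid by ``coordinate_spread_deg``.
    """
    params = params or MetacommunityParams()
    params.validate()
    rng = np.random.default_rng(seed)
    K = params.n_provinces
    n_sites = K * params.sites_per_province
    n_species = K * params.endemics_per_province + params.cosmopolitan_species

    site_ids = [f"S{p + 1:02d}_{i + 1:02d}" for p in range(K)
                for i in range(params.sites_per_province)]
    species_ids = [
        f"endemic_p{p + 1:02d}_{e + 1:02d}"
        for p in range(K)
        for e in range(params.endemics_per_province)
    ] + [f"cosmo_{c + 1:02d}" for c in range(params.cosmopolitan_species)]

    prob = np.empty((n_sites, n_species))
    labels: dict[str, int] = {}
    for idx, sid in enumerate(site_ids):
        p = idx // params.sites_per_province
        labels[sid] = p + 1
        for q in range(K):
            block = slice(
                q * params.endemics_per_province, (q + 1) * params.endemics_per_province
            )
            own = params.endemicity if q == p else (1.0 - params.endemicity)
            prob[idx, block] = own * params.detection_prob
        prob[idx, K * params.endemics_per_province :] = params.detection_prob
    occurrences = (rng.random((n_sites, n_species)) < prob).astype(float)

    centroids = _province_centroids(params)
    sites = []
    for idx, sid in enumerate(site_ids):
        lat0, lon0 = centroids[idx // params.sites_per_province]
        lat = float(
            np.clip(lat0 + rng.uniform(-1, 1) * params.coordinate_spread_deg, -89, 89)
        )
        lon = float(
            (lon0 + rng.uniform(-1, 1) * params.coordinate_spread_deg + 180.0) % 360.0
            - 180.0
        )
        sites.append(SiteRecord(sid, lat, lon, region_label=f"province_{labels[sid]}"))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # rare all-zero rows are fine
        matrix = CommunityMatrix(
            site_ids=site_ids, species_ids=species_ids, occurrences=occurrences
        )
    return SyntheticMetacommunity(
        matrix=matrix,
        true_labels=labels,
        sites=sites,
        params=params,
        seed=seed,
        province_centroids=centroids,
    )


def _tn93_rate_matrix(
    freqs: np.ndarray, kappa_purine: float, kappa_pyrimidine: float
) -> np.ndarray:
    """TN93 generator in ACGT order, scaled to one expected substitution per unit time."""
    A, C, G, T = range(4)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            pair = {i, j}
            if pair == {A, G}:
                rate = kappa_purine
            elif pair == {C, T}:
                rate = kappa_pyrimidine
            else:
                rate = 1.0
            Q[i, j] = rate * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(freqs @ np.diag(Q))
    return Q / mu


def generate_pair_alignment(
    length: int = 1000,
    target_distance: float = 0.05,
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    kappa_purine: float = 2.0,
    kappa_pyrimidine: float = 2.0,
    seed: int = 0,
    ids: tuple[str, str] = ("taxon_a", "taxon_b"),
) -> AlignedSeqSet:
    """Simulate two sequences diverged by ``target_distance`` substitutions/site.

    An ancestor is drawn from the base frequencies and each descendant
    evolves independently for half the target distance under the TN93
    process, so the expected pairwise distance equals the target.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    if target_distance < 0:
        raise ValueError("target_distance must be >= 0")
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("freqs must be four positive values summing to 1")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(4, size=length, p=pi)
    if target_distance == 0:
        rows = ["".join("ACGT"[b] for b in ancestor)] * 2
        return AlignedSeqSet(ids=list(ids), rows=rows)
    Q = _tn93_rate_matrix(pi, kappa_purine, kappa_pyrimidine)
    P = expm(Q * (target_distance / 2.0))
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    rows = []
    for _ in range(2):
        u = rng.random(length)
        seq = (u[:, None] > cum[ancestor]).sum(axis=1)
        rows.append("".join("ACGT"[b] for b in seq))
    return AlignedSeqSet(ids=list(ids), rows=rows)
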