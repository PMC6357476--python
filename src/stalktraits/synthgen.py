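"""Synthetic ground-truthed inputs for the stalk-trait pipeline.

Three generators, each deterministic under a fixed seed:

* :func:`render_section_image` — a flatbed-scan-like grayscale image of a
  stalk internode cross section: a bright rind annulus around a darker pith
  disc, studded with Gaussian-brightness vascular bundles, plus additive
  Gaussian noise, quantised to 8-bit.
* :func:`simulate_trait_table` — a balanced multi-environment trial table
  following ``y = mu + G + E + R(E) + GxE + eps`` with independent normal
  effects of specified variances.
* :func:`simulate_pileup` — per-site, per-individual allele read counts with
  Poisson depth and a per-read sequencing error rate, with the true diploid
  genotypes retained as ground truth.

Every generator returns the ground truth it drew, so downstream estimators
can be tested by recovery rather than by eye.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imagetraits import CrossSectionImage

ALLELES = ("A", "C", "G", "T")

__all__ = [
    "ImageSpec",
    "BundleTruth",
    "GroundTruthRecord",
    "TraitSimSpec",
    "TraitTableResult",
    "PileupSimSpec",
    "PileupResult",
    "BundlePlacementError",
    "render_section_image",
    "simulate_trait_table",
    "simulate_pileup",
]


class BundlePlacementError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the bundle spacing."""


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of a synthetic cross-section scan.

    Defaults draw a 2.2 x 2.0 cm stalk (the panel mean stalk diameter is
    near 2.35 cm) with a 0.30 cm rind on a 512 px square canvas at
    0.005 cm/px, 30 bundles with FWHM-scale areas near 1e-3 cm^2, and
    noise one tenth of the weakest bundle amplitude.
    """

    height_px: int = 512
    width_px: int = 512
    scale_cm_per_px: float = 0.005
    stalk_semi_axes_cm: tuple[float, float] = (1.1, 1.0)
    rind_thickness_cm: float = 0.30
    rind_intensity: float = 230.0
    pith_intensity: float = 90.0
    background_intensity: float = 20.0
    noise_sd: float = 6.0
    bundle_count: int = 30
    bundle_amplitude_range: tuple[float, float] = (60.0, 100.0)
    bundle_sigma_range_cm: tuple[float, float] = (0.012, 0.020)
    bundle_min_spacing_cm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.scale_cm_per_px <= 0:
            raise ValueError("scale_cm_per_px must be positive")
        a, b = self.stalk_semi_axes_cm
        if a <= 0 or b <= 0:
            raise ValueError("stalk semi-axes must be positive")
        if not 0 < self.rind_thickness_cm < min(a, b):
            raise ValueError("rind thickness must be in (0, min(a, b))")
        if self.pith_intensity >= self.rind_intensity:
            raise ValueError("pith must be darker than rind")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bundle_count < 0:
            raise ValueError("bundle_count must be non-negative")
        lo, hi = self.bundle_sigma_range_cm
        if lo <= 0 or hi < lo:
            raise ValueError("bundle_sigma_range_cm must be positive and ordered")
        if self.bundle_min_spacing_cm <= 0:
            raise ValueError("bundle_min_spacing_cm must be positive")
        # the outer ellipse must fit inside the canvas
        s = self.scale_cm_per_px
        cx = (self.width_px - 1) / 2 * s
        cy = (self.height_px - 1) / 2 * s
        if a > cx or b > cy:
            raise ValueError("stalk ellipse does not fit inside the image")


@dataclass(frozen=True)
class BundleTruth:
    """One drawn vascular bundle: centre (x, y) cm, 2x2 covariance cm^2, amplitude."""

    center_cm: tuple[float, float]
    covariance_cm2: tuple[tuple[float, float], tuple[float, float]]
    amplitude: float

    @property
    def sigma(self) -> np.ndarray:
        return np.asarray(self.covariance_cm2, dtype=float)

    def rim_area_cm2(self, rim_fraction: float) -> float:
        """Analytic ellipse area at the rim where brightness drops to
        ``rim_fraction`` of the peak: pi * 2 ln(1/f) * sqrt(det Sigma)."""
        if not 0 < rim_fraction < 1:
            raise ValueError("rim_fraction must lie in (0, 1)")
        det = float(np.linalg.det(self.sigma))
        return math.pi * 2.0 * math.log(1.0 / rim_fraction) * math.sqrt(det)


@dataclass(frozen=True)
class GroundTruthRecord:
    diameter_cm: float
    rind_thickness_cm: float
    bundles: tuple[BundleTruth, ...]
    cross_section_area_cm2: float
    bundle_density_per_cm2: float

    def bundle_centers(self) -> np.ndarray:
        return np.array([b.center_cm for b in self.bundles], dtype=float).reshape(-1, 2)

    def bundle_areas_cm2(self, rim_fraction: float) -> np.ndarray:
        return np.array([b.rim_area_cm2(rim_fraction) for b in self.bundles])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthRecord":
        d = json.loads(text)
        bundles = tuple(
            BundleTruth(
                center_cm=tuple(b["center_cm"]),
                covariance_cm2=tuple(tuple(row) for row in b["covariance_cm2"]),
                amplitude=b["amplitude"],
            )
            for b in d["bundles"]
        )
        return cls(
            diameter_cm=d["diameter_cm"],
            rind_thickness_cm=d["rind_thickness_cm"],
            bundles=bundles,
            cross_section_area_cm2=d["cross_section_area_cm2"],
            bundle_density_per_cm2=d["bundle_density_per_cm2"],
        )


def _place_bundle_centers(
    rng: np.random.Generator,
    n: int,
    semi_axes: tuple[float, float],
    center: tuple[float, float],
    min_spacing: float,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Rejection-sample ``n`` points inside an ellipse with a minimum
    pairwise spacing (Poisson-disc style)."""
    ax, ay = semi_axes
    cx, cy = center
    if ax <= 0 or ay <= 0:
        raise BundlePlacementError(
            "pith region too small for the requested bundle sigma/spacing margins"
        )
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise BundlePlacementError(
                f"could not place {n} bundle centers with min spacing "
                f"{min_spacing} cm inside semi-axes ({ax:.3f}, {ay:.3f}) cm "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        x = cx + (rng.uniform(-1, 1)) * ax
        y = cy + (rng.uniform(-1, 1)) * ay
        if ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 > 1.0:
            continue
        if any((x - px) ** 2 + (y - py) ** 2 < min_spacing**2 for px, py in placed):
            continue
        placed.append((x, y))
    return np.asarray(placed, dtype=float).reshape(-1, 2)


def render_section_image(spec: ImageSpec) -> tuple[CrossSectionImage, GroundTruthRecord]:
    """Render a synthetic cross-section scan and its exact ground truth.

    The intensity model is piecewise constant (background / rind annulus /
    pith disc, assigned by pixel-centre membership) plus, per bundle, an
    additive anisotropic Gaussian ``A * exp(-0.5 d' Sigma^-1 d)``, plus
    i.i.d. Gaussian noise. The result is clipped to [0, 255] and rounded to
    the 8-bit grid.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.scale_cm_per_px
    h, w = spec.height_px, spec.width_px
    a, b = spec.stalk_semi_axes_cm
    t = spec.rind_thickness_cm
    cx = (w - 1) / 2 * s
    cy = (h - 1) / 2 * s

    xs = np.arange(w) * s
    ys = np.arange(h) * s
    X, Y = np.meshgrid(xs, ys)
    outer = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    inner = ((X - cx) / (a - t)) ** 2 + ((Y - cy) / (b - t)) ** 2 <= 1.0

    img = np.full((h, w), float(spec.background_intensity))
    img[outer] = spec.rind_intensity
    img[inner] = spec.pith_intensity

    sig_lo, sig_hi = spec.bundle_sigma_range_cm
    margin = 2.0 * sig_hi  # keep bundle mass inside the pith
    centers = _place_bundle_centers(
        rng,
        spec.bundle_count,
        (a - t - margin, b - t - margin),
        (cx, cy),
        spec.bundle_min_spacing_cm,
    )

    bundles: list[BundleTruth] = []
    amp_lo, amp_hi = spec.bundle_amplitude_range
    for bx, by in centers:
        amp = float(rng.uniform(amp_lo, amp_hi))
        sx = float(rng.uniform(sig_lo, sig_hi))
        sy = float(rng.uniform(sig_lo, sig_hi))
        phi = float(rng.uniform(0.0, math.pi))
        c, sn = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -sn], [sn, c]])
        cov = rot @ np.diag([sx**2, sy**2]) @ rot.T
        cov_inv = np.linalg.inv(cov)

        # evaluate on a local window only (+-4 sigma_max)
        reach = 4.0 * max(sx, sy)
        c0 = max(0, int((bx - reach) / s))
        c1 = min(w, int((bx + reach) / s) + 2)
        r0 = max(0, int((by - reach) / s))
        r1 = min(h, int((by + reach) / s) + 2)
        dx = xs[c0:c1] - bx
        dy = ys[r0:r1] - by
        DX, DY = np.meshgrid(dx, dy)
        q = (
            cov_inv[0, 0] * DX**2
            + 2.0 * cov_inv[0, 1] * DX * DY
            + cov_inv[1, 1] * DY**2
        )
        img[r0:r1, c0:c1] += amp * np.exp(-0.5 * q)
        bundles.append(
            BundleTruth(
                center_cm=(float(bx), float(by)),
                covariance_cm2=tuple(tuple(float(v) for v in row) for row in cov),
                amplitude=amp,
            )
        )

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.rint(np.clip(img, 0.0, 255.0))

    area = math.pi * a * b
    truth = GroundTruthRecord(
        diameter_cm=2.0 * max(a, b),
        rind_thickness_cm=t,
        bundles=tuple(bundles),
        cross_section_area_cm2=area,
        bundle_density_per_cm2=len(bundles) / area,
    )
    return CrossSectionImage(intensities=img, scale_cm_per_px=s), truth


# ---------------------------------------------------------------------------
# Multi-environment trait tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSimSpec:
    """Balanced genotype x environment x replication trial.

    The observation model is ``y_ijk = mu + G_i + E_j + R_k(j) + GE_ij +
    eps_ijk`` with every effect drawn independently normal with its stated
    variance; replications are nested within environments.
    """

    n_genotypes: int = 500
    n_environments: int = 3
    n_replications: int = 2
    grand_mean: float = 0.0
    var_G: float = 1.0
    var_E: float = 0.5
    var_RwithinE: float = 0.25
    var_GE: float = 0.5
    var_e: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_environments, self.n_replications) < 1:
            raise ValueError("design sizes must be positive")
        for name in ("var_G", "var_E", "var_RwithinE", "var_GE", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TraitTableResult:
    """Simulated table plus the effects actually drawn (the ground truth)."""

    table: pd.DataFrame  # columns: genotype, environment, replication, value
    genotype_effects: pd.Series
    environment_effects: pd.Series
    rep_effects: pd.DataFrame  # environments x replications
    ge_effects: pd.DataFrame  # genotypes x environments


def simulate_trait_table(spec: TraitSimSpec) -> TraitTableResult:
    rng = np.random.default_rng(spec.seed)
    g, y, r = spec.n_genotypes, spec.n_environments, spec.n_replications
    G = rng.normal(0.0, math.sqrt(spec.var_G), g)
    E = rng.normal(0.0, math.sqrt(spec.var_E), y)
    R = rng.normal(0.0, math.sqrt(spec.var_RwithinE), (y, r))
    GE = rng.normal(0.0, math.sqrt(spec.var_GE), (g, y))
    eps = rng.normal(0.0, math.sqrt(spec.var_e), (g, y, r))

    values = (
        spec.grand_mean
        + G[:, None, None]
        + E[None, :, None]
        + R[None, :, :]
        + GE[:, :, None]
        + eps
    )

    geno_ids = [f"G{i + 1:04d}" for i in range(g)]
    env_ids = [f"E{j + 1}" for j in range(y)]
    gi, ej, rk = np.meshgrid(np.arange(g), np.arange(y), np.arange(r), indexing="ij")
    table = pd.DataFrame(
        {
            "genotype": np.array(geno_ids)[gi.ravel()],
            "environment": np.array(env_ids)[ej.ravel()],
            "replication": rk.ravel() + 1,
            "value": values.ravel(),
        }
    )
    return TraitTableResult(
        table=table,
        genotype_effects=pd.Series(G, index=geno_ids, name="G"),
        environment_effects=pd.Series(E, index=env_ids, name="E"),
        rep_effects=pd.DataFrame(R, index=env_ids, columns=range(1, r + 1)),
        ge_effects=pd.DataFrame(GE, index=geno_ids, columns=env_ids),
    )


# ---------------------------------------------------------------------------
# Allele read-count pileups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PileupSimSpec:
    """Read-count simulation for an inbred-style panel.

    Per site an alternate-allele frequency ``p`` applies; individuals get
    genotypes at Hardy-Weinberg proportions (hom-ref, het, hom-alt). Depth
    is Poisson per site x individual; each read reports the true allele
    (50:50 between the two for heterozygotes) and flips to a uniformly
    chosen other base with probability ``error_rate``.
    """

    n_sites: int = 50
    n_individuals: int = 40
    mean_depth: float = 10.0
    true_allele_freqs: float | Sequence[float] = 0.3
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_individuals < 1:
            raise ValueError("n_sites and n_individuals must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        freqs = np.atleast_1d(np.asarray(self.true_allele_freqs, dtype=float))
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("true_allele_freqs must lie in [0, 1]")
        if freqs.size not in (1, self.n_sites):
            raise ValueError("true_allele_freqs must be scalar or one per site")


@dataclass(frozen=True)
class PileupResult:
    counts: pd.DataFrame  # long: site, individual, allele, count (non-zero rows)
    truth: pd.DataFrame  # sites x individuals, 'A' or 'A/C' style genotypes
    site_alleles: pd.DataFrame  # site, ref, alt


def simulate_pileup(spec: PileupSimSpec) -> PileupResult:
    rng = np.random.default_rng(spec.seed)
    n_s, n_i = spec.n_sites, spec.n_individuals
    freqs = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.true_allele_freqs, dtype=float)), (n_s,)
    )
    sites = [f"s{k + 1:04d}" for k in range(n_s)]
    inds = [f"ind{k + 1:03d}" for k in range(n_i)]

    allele_idx = np.arange(4)
    rows: list[tuple[str, str, str, int]] = []
    truth = np.empty((n_s, n_i), dtype=object)
    ref_alt: list[tuple[str, str]] = []

    for si, site in enumerate(sites):
        ref_i, alt_i = rng.choice(4, size=2, replace=False)
        ref, alt = ALLELES[ref_i], ALLELES[alt_i]
        ref_alt.append((ref, alt))
        p = freqs[si]
        # alt-allele dosage at Hardy-Weinberg proportions
        dosage = rng.choice(3, size=n_i, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
        depth = rng.poisson(spec.mean_depth, size=n_i)
        alt_prob = dosage / 2.0
        alt_reads = rng.binomial(depth, alt_prob)
        ref_reads = depth - alt_reads
        for ii in range(n_i):
            if dosage[ii] == 0:
                truth[si, ii] = ref
            elif dosage[ii] == 2:
                truth[si, ii] = alt
            else:
                truth[si, ii] = "/".join(sorted((ref, alt)))
            counts = np.zeros(4, dtype=int)
            for true_i, n_reads in ((ref_i, int(ref_reads[ii])), (alt_i, int(alt_reads[ii]))):
                if n_reads == 0:
                    continue
                n_err = rng.binomial(n_reads, spec.error_rate)
                counts[true_i] += n_reads - n_err
                if n_err:
                    others = allele_idx[allele_idx != true_i]
                    counts[others] += rng.multinomial(n_err, [1 / 3] * 3)
            for ai in np.nonzero(counts)[0]:
                rows.append((site, inds[ii], ALLELES[ai], int(counts[ai])))

    counts_df = pd.DataFrame(rows, columns=["site", "individual", "allele", "count"])
    truth_df = pd.DataFrame(truth, index=sites, columns=inds)
    site_df = pd.DataFrame(ref_alt, columns=["ref", "alt"], index=sites)
    site_df.index.name = "site"
    return PileupResult(counts=counts_df, truth=truth_df, site_alleles=site_df)
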