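"""Synthetic two-channel punctate images and expression matrices with ground truth.

The image simulator renders isotropic Gaussian puncta on a linear background,
optionally adds Gaussian or Poisson noise, quantizes to the camera bit depth,
and returns a truth registry linking each planted spot to its coincidental
partner (if any) in the other channel.  The expression simulator draws a
genes x samples log-scale matrix from a multivariate normal with a planted
correlation structure and a planted dead-vs-alive group shift.

Every simulation takes an explicit seed; there is no hidden global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix

__all__ = [
    "SpotTruth",
    "ImageSimConfig",
    "ExprSimConfig",
    "simulate_image_pair",
    "simulate_expression",
    "truth_to_frame",
    "write_truth_csv",
    "write_image_pair_tiff",
    "write_image_pair_png",
    "load_config",
]

_MAX_PLACEMENT_TRIES = 10_000


@dataclass(frozen=True)
class SpotTruth:
    """Ground truth for one planted punctum.

    ``row``/``col`` are sub-pixel centre coordinates (0-based, row downward);
    ``partner_id`` links the coincidental partner spot in the other channel,
    or None for a single-channel spot.  Partner links are symmetric and
    one-to-one.
    """

    spot_id: int
    channel: str  # "A" or "B"
    row: float
    col: float
    amplitude: float
    sigma: float
    partner_id: int | None = None


@dataclass(frozen=True)
class ImageSimConfig:
    """Conditions for one simulated two-channel image pair.

    Defaults mirror the acquisition geometry the pipeline targets
    (768 x 582 px, 8-bit camera) with puncta bright enough to clear the
    10 AU detection criterion.  ``true_coincident_fraction`` of the A spots
    receive a B partner displaced by a per-axis normal draw of standard
    deviation ``partner_jitter`` (truncated at two standard deviations so a
    planted pair remains geometrically coincidental after discretization).
    Spots are otherwise placed uniformly, with ``min_separation`` (default
    4 x the largest sigma) enforced between same-channel centres and between
    non-partner centres across channels, so the planted pairing is the only
    coincidence structure in the image.
    """

    height: int = 582
    width: int = 768
    n_spots_A: int = 50
    n_spots_B: int = 50
    true_coincident_fraction: float = 0.5
    partner_jitter: float = 0.5
    amplitude_range: tuple[float, float] = (30.0, 120.0)
    sigma_range: tuple[float, float] = (1.0, 2.0)
    background_level: float = 10.0
    background_gradient: float = 0.0
    noise_model: str = "none"
    noise_scale: float = 2.0
    seed: int = 0
    min_separation: float | None = None
    bit_depth: int = 8
    edge_pad: int = 10  # keep spot centres clear of the border

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_coincident_fraction <= 1.0:
            raise ValueError("true_coincident_fraction must be in [0, 1]")
        if self.partner_jitter < 0:
            raise ValueError("partner_jitter must be >= 0")
        for name in ("amplitude_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")
        if self.sigma_range[0] <= 0:
            raise ValueError("sigma_range lower bound must be > 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be 'none', 'gaussian' or 'poisson'")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.min_separation is None:
            object.__setattr__(self, "min_separation", 4.0 * self.sigma_range[1])

    @property
    def n_coincident(self) -> int:
        return int(round(self.true_coincident_fraction * self.n_spots_A))


@dataclass(frozen=True)
class ExprSimConfig:
    """Conditions for one simulated log-scale expression matrix.

    ``target_correlation`` is the planted gene-gene Pearson correlation
    matrix (symmetric, unit diagonal, PSD).  The first ``n_dead`` samples
    are labelled dead and receive ``group_shift`` additively per gene; the
    last ``n_unknown`` samples are labelled unknown (emulating patients of
    undetermined status).  Sample-size and grouping defaults follow a
    68-patient cohort with 10 deceased, 57 alive and 1 undetermined.
    """

    gene_names: tuple[str, ...] = (
        "PRKACA",
        "PRKAR1A",
        "PRKAR1B",
        "PRKAR2A",
        "PRKAR2B",
    )
    n_samples: int = 68
    target_correlation: np.ndarray | None = None  # default: identity
    means: np.ndarray | float = 8.0
    sds: np.ndarray | float = 1.0
    n_dead: int = 10
    n_unknown: int = 1
    group_shift: np.ndarray | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = len(self.gene_names)
        if len(set(self.gene_names)) != g:
            raise ValueError("gene_names must be unique")
        corr = self.target_correlation
        if corr is None:
            corr = np.eye(g)
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (g, g):
            raise ValueError(f"target_correlation must be {g}x{g}")
        if not np.allclose(corr, corr.T):
            raise ValueError("target_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("target_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("target_correlation is not positive semi-definite")
        object.__setattr__(self, "target_correlation", corr)
        object.__setattr__(
            self, "means", np.broadcast_to(np.asarray(self.means, float), (g,)).copy()
        )
        sds = np.broadcast_to(np.asarray(self.sds, float), (g,)).copy()
        if (sds < 0).any():
            raise ValueError("sds must be non-negative")
        object.__setattr__(self, "sds", sds)
        object.__setattr__(
            self,
            "group_shift",
            np.broadcast_to(np.asarray(self.group_shift, float), (g,)).copy(),
        )
        if self.n_dead + self.n_unknown >= self.n_samples:
            raise ValueError("n_dead + n_unknown must be < n_samples")


def _place_points(
    rng: np.random.Generator,
    n: int,
    cfg: ImageSimConfig,
    existing: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Uniform dart-throwing placement respecting min_separation to `existing`."""
    lo_r, hi_r = cfg.edge_pad, cfg.height - 1 - cfg.edge_pad
    lo_c, hi_c = cfg.edge_pad, cfg.width - 1 - cfg.edge_pad
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("image too small for the edge padding")
    placed: list[tuple[float, float]] = []
    sep2 = cfg.min_separation**2
    for _ in range(n):
        for _try in range(_MAX_PLACEMENT_TRIES):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= sep2 for pr, pc in existing) and all(
                (r - pr) ** 2 + (c - pc) ** 2 >= sep2 for pr, pc in placed
            ):
                placed.append((r, c))
                break
        else:
            raise ValueError(
                f"could not place {n} spots with min_separation="
                f"{cfg.min_separation} px in a {cfg.height}x{cfg.width} image: "
                "the minimum-separation constraint is infeasible at this density"
            )
    return placed


def _truncated_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """Normal(0, sd) truncated at +/- 2 sd per component (resampling)."""
    if sd == 0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > 2 * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > 2 * sd
    return out


def _render(
    cfg: ImageSimConfig, spots: list[SpotTruth], rng: np.random.Generator
) -> np.ndarray:
    """Render one channel: linear background + Gaussian spots, noise, clip, quantize."""
    h, w = cfg.height, cfg.width
    img = np.full((h, w), float(cfg.background_level))
    if cfg.background_gradient:
        img += cfg.background_gradient * np.arange(w)[None, :]
    for s in spots:
        rad = int(np.ceil(4 * s.sigma)) + 1
        r0, r1 = max(0, int(s.row) - rad), min(h, int(s.row) + rad + 1)
        c0, c1 = max(0, int(s.col) - rad), min(w, int(s.col) + rad + 1)
        rr = np.arange(r0, r1)[:, None] - s.row
        cc = np.arange(c0, c1)[None, :] - s.col
        img[r0:r1, c0:c1] += s.amplitude * np.exp(
            -(rr**2 + cc**2) / (2 * s.sigma**2)
        )
    if cfg.noise_model == "gaussian":
        img += rng.normal(0.0, cfg.noise_scale, img.shape)
    elif cfg.noise_model == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    hi = 2**cfg.bit_depth - 1
    return np.clip(np.round(img), 0, hi)


def simulate_image_pair(cfg: ImageSimConfig):
    """Simulate one two-channel image pair with a known coincidence structure.

    Returns ``(image_a, image_b, truth)`` where the images are quantized
    2-D arrays of identical shape and ``truth`` is the list of SpotTruth
    records (A spots first).  Exactly
    ``round(true_coincident_fraction * n_spots_A)`` A spots carry a B
    partner; partner links are symmetric and one-to-one.
    """
    rng = np.random.default_rng(cfg.seed)
    n_coinc = cfg.n_coincident
    if n_coinc > cfg.n_spots_B:
        raise ValueError(
            f"round(true_coincident_fraction * n_spots_A) = {n_coinc} exceeds "
            f"n_spots_B = {cfg.n_spots_B}"
        )

    pos_a = _place_points(rng, cfg.n_spots_A, cfg, existing=[])
    # which A spots get a partner: the first n_coinc after a seeded shuffle
    partner_idx = rng.permutation(cfg.n_spots_A)[:n_coinc]
    jit_r = _truncated_normal(rng, cfg.partner_jitter, n_coinc)
    jit_c = _truncated_normal(rng, cfg.partner_jitter, n_coinc)
    pos_b_partner = [
        (pos_a[i][0] + jit_r[k], pos_a[i][1] + jit_c[k])
        for k, i in enumerate(partner_idx)
    ]
    # B-only spots keep min_separation from every A spot too, so the planted
    # pairing is the only coincidence structure
    pos_b_only = _place_points(rng, cfg.n_spots_B - n_coinc, cfg, existing=pos_a)

    def draw_amp_sigma(n):
        return (
            rng.uniform(*cfg.amplitude_range, n),
            rng.uniform(*cfg.sigma_range, n),
        )

    amp_a, sig_a = draw_amp_sigma(cfg.n_spots_A)
    amp_b, sig_b = draw_amp_sigma(cfg.n_spots_B)

    truth: list[SpotTruth] = []
    next_id = 0
    a_ids = []
    for i, (r, c) in enumerate(pos_a):
        truth.append(SpotTruth(next_id, "A", r, c, float(amp_a[i]), float(sig_a[i])))
        a_ids.append(next_id)
        next_id += 1
    b_spots: list[SpotTruth] = []
    for k, i in enumerate(partner_idx):
        r, c = pos_b_partner[k]
        b_spots.append(
            SpotTruth(
                next_id, "B", r, c, float(amp_b[k]), float(sig_b[k]),
                partner_id=a_ids[i],
            )
        )
        truth[i] = dataclasses.replace(truth[i], partner_id=next_id)
        next_id += 1
    for k, (r, c) in enumerate(pos_b_only, start=n_coinc):
        b_spots.append(SpotTruth(next_id, "B", r, c, float(amp_b[k]), float(sig_b[k])))
        next_id += 1
    truth.extend(b_spots)

    image_a = _render(cfg, [s for s in truth if s.channel == "A"], rng)
    image_b = _render(cfg, [s for s in truth if s.channel == "B"], rng)
    return image_a, image_b, truth


def simulate_expression(cfg: ExprSimConfig) -> ExpressionMatrix:
    """Draw a genes x samples log-scale matrix with the planted correlation.

    Values come from a multivariate normal with covariance
    ``diag(sds) @ target_correlation @ diag(sds)``; dead-group columns then
    receive ``group_shift``.  Statuses are assigned deterministically:
    the first ``n_dead`` samples dead, the last ``n_unknown`` unknown.
    """
    rng = np.random.default_rng(cfg.seed)
    g = len(cfg.gene_names)
    cov = np.diag(cfg.sds) @ cfg.target_correlation @ np.diag(cfg.sds)
    vals = rng.multivariate_normal(
        cfg.means, cov, size=cfg.n_samples, method="svd"
    ).T  # genes x samples
    status = np.array(
        ["dead"] * cfg.n_dead
        + ["alive"] * (cfg.n_samples - cfg.n_dead - cfg.n_unknown)
        + ["unknown"] * cfg.n_unknown
    )
    vals[:, status == "dead"] += np.asarray(cfg.group_shift)[:, None]
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    values = pd.DataFrame(vals, index=list(cfg.gene_names), columns=samples)
    return ExpressionMatrix(values=values, sample_status=list(status))


# ---------------------------------------------------------------------------
# writers / config IO


def truth_to_frame(truth: list[SpotTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "channel": s.channel,
                "row": s.row,
                "col": s.col,
                "amplitude": s.amplitude,
                "sigma": s.sigma,
                "partner_id": "" if s.partner_id is None else s.partner_id,
            }
            for s in truth
        ],
        columns=["spot_id", "channel", "row", "col", "amplitude", "sigma", "partner_id"],
    )


def write_truth_csv(truth: list[SpotTruth], path: str | Path) -> None:
    """Truth registry CSV; coordinates are 0-based (row, col), row downward."""
    truth_to_frame(truth).to_csv(path, index=False)


def _as_uint(img: np.ndarray, bit_depth: int) -> np.ndarray:
    return img.astype(np.uint8 if bit_depth == 8 else np.uint16)


def write_image_pair_tiff(
    image_a: np.ndarray,
    image_b: np.ndarray,
    out_dir: str | Path,
    stem: str = "pair",
    bit_depth: int = 8,
) -> tuple[Path, Path]:
    """One single-plane grayscale TIFF per channel."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pa = out / f"{stem}_A.tif"
    pb = out / f"{stem}_B.tif"
    tifffile.imwrite(pa, _as_uint(image_a, bit_depth))
    tifffile.imwrite(pb, _as_uint(image_b, bit_depth))
    return pa, pb


def write_image_pair_png(
    image_a: np.ndarray,
    image_b: np.ndarray,
    path: str | Path,
    bit_depth: int = 8,
) -> Path:
    """RGB PNG with channel A on red, B on green, blue empty."""
    import imageio.v3 as iio

    rgb = np.stack(
        [
            _as_uint(image_a, bit_depth),
            _as_uint(image_b, bit_depth),
            np.zeros_like(_as_uint(image_a, bit_depth)),
        ],
        axis=-1,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return path


def load_config(path: str | Path, kind: str):
    """Read an ImageSimConfig or ExprSimConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if kind == "image":
        for key in ("amplitude_range", "sigma_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return ImageSimConfig(**raw)
    if kind == "expression":
        if "gene_names" in raw:
            raw["gene_names"] = tuple(raw["gene_names"])
        if raw.get("target_correlation") is not None:
            raw["target_correlation"] = np.asarray(raw["target_correlation"], float)
        return ExprSimConfig(**raw)
    raise ValueError("kind must be 'image' or 'expression'")
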