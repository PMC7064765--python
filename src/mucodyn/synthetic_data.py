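"""Synthetic fixtures: growth-parameter tables, compositional abundance
tables with planted rank-correlation block structure, and paired
observed/predicted vectors for exercising the validation statistics.

Abundance tables come from a Gaussian copula: a latent multivariate
normal with block-structured correlation is pushed through per-taxon
log-normal marginals and then closed to 100% per sample. Because the
downstream network method is rank-based, only the rank structure needs
to be controlled, and closure (division by a positive per-sample total)
preserves within-sample ranks. Cross-sample correlations survive closure
only approximately: positive planted blocks keep nearly their target rho,
while negative ones are attenuated by the shared-total compositional
effect (plant a stronger |rho| or use more taxa to compensate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from mucodyn.model_core import GrowthParams
from mucodyn.network_inference import AbundanceTable

__all__ = [
    "CorrelationBlock",
    "SynthSpec",
    "gen_growth_params",
    "gen_abundance_table",
    "gen_paired_validation_set",
    "growth_params_frame",
]


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of taxa sharing a planted pairwise rank correlation.

    ``rho`` is the target latent correlation magnitude in (0, 1];
    ``sign`` of -1 plants negative pairwise correlations (only feasible
    for small blocks: the equicorrelation matrix must stay positive
    semi-definite, requiring ``-1/(m-1) <= sign*rho``).
    """

    members: tuple[int, ...]
    rho: float
    sign: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError(f"target |rho| must be in (0,1], got {self.rho}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if len(set(self.members)) != len(self.members):
            raise ValueError("block members must be distinct")


@dataclass
class SynthSpec:
    """Recipe for one synthetic compositional abundance table."""

    n_samples: int
    n_taxa: int
    blocks: list[CorrelationBlock] = field(default_factory=list)
    lognormal_mean: float = 1.0
    lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for b in self.blocks:
            if seen & set(b.members):
                raise ValueError("correlation blocks must be disjoint")
            seen |= set(b.members)
            if any(m < 0 or m >= self.n_taxa for m in b.members):
                raise ValueError("block member index out of range")

    def correlation_matrix(self) -> np.ndarray:
        corr = np.eye(self.n_taxa)
        for b in self.blocks:
            r = b.sign * b.rho
            for i in b.members:
                for j in b.members:
                    if i != j:
                        corr[i, j] = r
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"planted correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g}); reduce |rho| or block size"
            )
        return corr

    def to_json(self) -> str:
        d = asdict(self)
        d["blocks"] = [
            {"members": list(b.members), "rho": b.rho, "sign": b.sign}
            for b in self.blocks
        ]
        return json.dumps(d, indent=2)


def gen_growth_params(
    n_taxa: int,
    mu_range: tuple[float, float] = (15.0, 35.0),
    sigma_range: tuple[float, float] = (2.0, 8.0),
    rmax_range: tuple[float, float] = (0.1, 2.0),
    seed: int = 0,
    taxon_ids: list[str] | None = None,
) -> list[GrowthParams]:
    """Uniformly sampled per-taxon (r_max, mu, sigma), deterministic per seed."""
    rng = np.random.default_rng(seed)
    if taxon_ids is None:
        taxon_ids = [f"taxon_{i:02d}" for i in range(n_taxa)]
    if len(taxon_ids) != n_taxa:
        raise ValueError("taxon_ids length must equal n_taxa")
    r_max = rng.uniform(*rmax_range, size=n_taxa)
    mu = rng.uniform(*mu_range, size=n_taxa)
    sigma = rng.uniform(*sigma_range, size=n_taxa)
    return [
        GrowthParams(taxon_id=t, r_max=float(r), mu=float(m), sigma=float(s))
        for t, r, m, s in zip(taxon_ids, r_max, mu, sigma)
    ]


def growth_params_frame(params: list[GrowthParams]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": [p.taxon_id for p in params],
            "r_max": [p.r_max for p in params],
            "mu": [p.mu for p in params],
            "sigma": [p.sigma for p in params],
        }
    )


def gen_abundance_table(spec: SynthSpec) -> AbundanceTable:
    """Compositional table with planted rank-correlation blocks.

    Latent draws Z ~ N(0, corr) are mapped to uniforms by the normal CDF
    and through log-normal quantile functions (per-taxon location spread
    over a decade so marginals differ), then each sample is closed to
    100%. Ranks within each taxon column are monotone in the latent
    normals, so Spearman correlations approach the planted values.
    """
    corr = spec.correlation_matrix()
    rng = np.random.default_rng(spec.seed)
    # sample via Cholesky with a tiny jitter if exactly singular
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(spec.n_taxa))
    z = rng.standard_normal((spec.n_samples, spec.n_taxa)) @ chol.T
    u = stats.norm.cdf(z)
    # distinct per-taxon log-normal locations keep marginal scales varied
    locs = spec.lognormal_mean + np.linspace(-1.0, 1.0, spec.n_taxa)
    raw = stats.lognorm.ppf(u, s=spec.lognormal_sigma, scale=np.exp(locs))
    closed = 100.0 * raw / raw.sum(axis=1, keepdims=True)
    # closure must not disturb within-sample rank order
    assert all(
        np.array_equal(np.argsort(r), np.argsort(c)) for r, c in zip(raw, closed)
    ), "closure changed within-sample rank order"
    return AbundanceTable(
        sample_ids=[f"sample_{i:03d}" for i in range(spec.n_samples)],
        taxon_ids=[f"taxon_{i:02d}" for i in range(spec.n_taxa)],
        values=closed,
    )


def gen_paired_validation_set(
    n: int,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (observed, predicted) vectors with a known linear relation.

    Predicted values are positive (log-normal); observed values are
    ``slope * predicted + intercept`` plus Gaussian noise.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    predicted = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    observed = slope * predicted + intercept + rng.normal(0.0, noise_sd, size=n)
    return observed, predicted
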