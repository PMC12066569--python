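"""Synthetic dataset bundles with planted low-rank structure.

The generator emulates the statistical assumption the model exploits:
similarity between entities reflects latent factors that also drive
associations.  Drugs and diseases get unit-norm latent factor rows U, V;
pairwise similarity is (1 + cos)/2 plus Gaussian noise (clipped to [0, 1],
symmetrised, unit diagonal), and associations are Bernoulli draws of
sigmoid(s * U_i.V_j + b) with b calibrated by bisection so the expected
positive rate hits the requested density.  The true factors are returned so
tests can use the oracle scorer U_i.V_j as a reference.

Default shape (100 drugs x 80 diseases, rank 8, density 0.05, noise 0.05)
is the package's reference condition: large enough for a clear planted
signal, small enough for repeated desk-scale training runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .datasets import (AssociationMatrix, DatasetBundle, FILE_NAMES,
                       SimilarityMatrix, write_matrix_file)

__all__ = ["SyntheticSpec", "generate", "write_bundle", "oracle_scores"]


@dataclass
class SyntheticSpec:
    n_drugs: int = 100
    n_diseases: int = 80
    latent_dim: int = 8
    assoc_density: float = 0.05
    noise_sd: float = 0.05
    seed: int = 0
    slope: float = 4.0  # fixed logistic slope s; only the offset is calibrated

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 < self.assoc_density < 0.5:
            raise ValueError("assoc_density must be in (0, 0.5)")
        if min(self.n_drugs, self.n_diseases) < self.latent_dim:
            raise ValueError("entity counts must be >= latent_dim")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _unit_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _similarity(factors: np.ndarray, noise_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    sim = (1.0 + factors @ factors.T) / 2.0
    if noise_sd > 0:
        noise = noise_sd * rng.standard_normal(sim.shape)
        sim = sim + (noise + noise.T) / 2.0
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def _calibrate_offset(logits: np.ndarray, density: float,
                      max_iter: int = 200) -> float:
    """Bisect the offset b so mean sigmoid(logits + b) == density."""
    lo, hi = -30.0, 30.0

    def rate(b):
        return float(np.mean(1.0 / (1.0 + np.exp(-(logits + b)))))

    if not rate(lo) <= density <= rate(hi):
        raise RuntimeError("offset calibration failed: density unreachable")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if rate(mid) < density:
            lo = mid
        else:
            hi = mid
    b = (lo + hi) / 2.0
    if abs(rate(b) - density) > 0.2 * density:
        raise RuntimeError("offset calibration did not converge")
    return b


def generate(spec: SyntheticSpec) -> DatasetBundle:
    """Draw a full bundle; ground-truth factors live in ``bundle.latent``."""
    rng = np.random.default_rng(spec.seed)
    u = _unit_rows(rng.standard_normal((spec.n_drugs, spec.latent_dim)))
    v = _unit_rows(rng.standard_normal((spec.n_diseases, spec.latent_dim)))
    drug_ids = [f"D{i + 1:04d}" for i in range(spec.n_drugs)]
    disease_ids = [f"S{j + 1:04d}" for j in range(spec.n_diseases)]
    drug_sim = SimilarityMatrix(drug_ids, _similarity(u, spec.noise_sd, rng))
    dis_sim = SimilarityMatrix(disease_ids,
                               _similarity(v, spec.noise_sd, rng))
    logits = spec.slope * (u @ v.T)
    b = _calibrate_offset(logits.ravel(), spec.assoc_density)
    p = 1.0 / (1.0 + np.exp(-(logits + b)))
    assoc = (rng.random(p.shape) < p).astype(int)
    if assoc.sum() == 0:
        raise RuntimeError("no positives drawn; density too low for size")
    return DatasetBundle(
        drug_sim=drug_sim,
        disease_sim=dis_sim,
        associations=AssociationMatrix(drug_ids, disease_ids, assoc),
        latent={"U": u, "V": v, "offset": b, "slope": spec.slope},
    )


def oracle_scores(bundle: DatasetBundle) -> np.ndarray:
    """Ground-truth affinity U V^T (only defined for synthetic bundles)."""
    if "U" not in bundle.latent:
        raise ValueError("bundle has no ground-truth factors")
    return bundle.latent["U"] @ bundle.latent["V"].T


def write_bundle(bundle: DatasetBundle, out_dir: str) -> None:
    """Emit the three-file dataset directory layout (round-trips exactly)."""
    os.makedirs(out_dir, exist_ok=True)
    write_matrix_file(bundle.drug_sim,
                      os.path.join(out_dir, FILE_NAMES["drug_sim"]))
    write_matrix_file(bundle.disease_sim,
                      os.path.join(out_dir, FILE_NAMES["disease_sim"]))
    write_matrix_file(bundle.associations,
                      os.path.join(out_dir, FILE_NAMES["associations"]))
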