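"""Shared helpers: seed handling and small numeric guards."""

from __future__ import annotations

import numpy as np

# Stage labels get stable, documented sub-seeds so that each pipeline stage is
# individually reproducible from the one user-facing seed.
_STAGE_OFFSETS = {
    "haplotypes": 1,
    "diplotypes": 2,
    "phenotypes": 3,
    "scan": 4,
    "conditional_scan": 5,
    "saap": 6,
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global run seed.

    Uses a SeedSequence keyed on (seed, stage offset); the mapping is fixed so
    rerunning a single stage with the same global seed reproduces its stream.
    """
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(seed), _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


def check_positive_definite(mat: np.ndarray, name: str = "matrix") -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() <= 0:
        raise ValueError(
            f"{name} must be positive definite (min eigenvalue {eigvals.min():.3g})"
        )
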