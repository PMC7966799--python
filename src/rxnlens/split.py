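"""Product-similarity-debiased train/test splitting.

Random splits of reaction corpora suffer from scaffold bias: near-identical
products land on both sides of the split, so held-out accuracy overstates
generalization.  The transfer split removes this: after a seeded random
split, every test reaction whose product is within Tanimoto similarity
sigma of any training product is moved to the training set, and the
initial split fraction is adjusted (by bisection) until the achieved
test fraction matches the target.  The returned split always satisfies

    max over test products of max Tanimoto to train products < sigma.

Products are featurized as Morgan fingerprints of radius 3 hashed to 1024
bits.  For diagnosing how similar the *transformations* (not just the
products) on the two sides are, reaction difference fingerprints — the
signed count-fingerprint difference products-minus-reactants — are also
provided, compared with a continuous Tanimoto.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .reaction_io import ReactionRecord, SmilesParseError

__all__ = [
    "ProductFingerprint",
    "SplitConfig",
    "SplitResult",
    "product_fingerprint",
    "tanimoto",
    "count_tanimoto",
    "reaction_difference_fingerprint",
    "tanimoto_transfer_split",
    "overlap_fraction",
]

_RADIUS = 3
_NBITS = 1024
_BIT_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=_RADIUS, fpSize=_NBITS)


@dataclass(frozen=True)
class ProductFingerprint:
    """Morgan bit fingerprint of a reaction's (first) product."""

    bits: np.ndarray  # bool vector of length `n_bits`
    radius: int = _RADIUS
    n_bits: int = _NBITS
    reaction_id: str = ""


@dataclass(frozen=True)
class SplitConfig:
    """Parameters of the Tanimoto transfer split."""

    sigma: float = 0.6
    target_test_fraction: float = 0.1
    initial_test_fraction: float | None = None  # default: the target
    seed: int = 0
    max_adjust_iterations: int = 20
    fraction_tolerance: float = 0.005  # 0.5 percentage points

    def __post_init__(self) -> None:
        if not 0 < self.sigma <= 1:
            raise ValueError("sigma must be in (0, 1]")
        if not 0 < self.target_test_fraction < 1:
            raise ValueError("target_test_fraction must be in (0, 1)")


@dataclass
class SplitResult:
    """A train/test partition with its cross-set similarity diagnostics."""

    train_ids: list[str]
    test_ids: list[str]
    achieved_test_fraction: float
    transferred_count: int
    max_cross_similarity: float
    sigma: float
    converged: bool  # target fraction reached within tolerance
    initial_test_fraction: float


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol


def product_fingerprint(product: str, reaction_id: str = "") -> ProductFingerprint:
    """Radius-3 / 1024-bit Morgan fingerprint; canonical-SMILES invariant."""
    fp = _BIT_GEN.GetFingerprintAsNumPy(_mol(product)).astype(bool)
    return ProductFingerprint(bits=fp, reaction_id=reaction_id)


def tanimoto(a, b) -> float:
    """|a AND b| / |a OR b| on bit vectors; 0 when both are empty."""
    a = a.bits if isinstance(a, ProductFingerprint) else np.asarray(a, dtype=bool)
    b = b.bits if isinstance(b, ProductFingerprint) else np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def count_tanimoto(a, b) -> float:
    """Continuous Tanimoto <a,b> / (|a|^2 + |b|^2 - <a,b>) for signed
    count vectors; 1 for identical non-zero vectors, 0 for two zeros."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        return 0.0
    return dot / denom


def _count_fp(smiles: str) -> np.ndarray:
    fp = _BIT_GEN.GetCountFingerprint(_mol(smiles))
    out = np.zeros(_NBITS, dtype=np.int64)
    for bit, count in fp.GetNonzeroElements().items():
        out[bit] = count
    return out


def reaction_difference_fingerprint(record: ReactionRecord) -> np.ndarray:
    """Signed count vector: sum of product fingerprints minus sum of
    reactant fingerprints (reagents excluded).  Unreacting spectators
    present on both sides cancel exactly."""
    vec = np.zeros(_NBITS, dtype=np.int64)
    for p in record.products:
        vec += _count_fp(p)
    for r in record.reactants:
        vec -= _count_fp(r)
    return vec


def _fingerprint_matrix(records) -> np.ndarray:
    """Packed bit matrix of first-product fingerprints, one row per record."""
    return np.vstack(
        [product_fingerprint(r.products[0]).bits for r in records]
    )


def _max_cross_tanimoto(test_fp: np.ndarray, train_fp: np.ndarray) -> np.ndarray:
    """For each test row, its maximum Tanimoto to any train row."""
    test_i = test_fp.astype(np.int32)
    train_i = train_fp.astype(np.int32)
    inter = test_i @ train_i.T
    pop_test = test_i.sum(axis=1)[:, None]
    pop_train = train_i.sum(axis=1)[None, :]
    union = pop_test + pop_train - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim.max(axis=1) if train_fp.shape[0] else np.zeros(test_fp.shape[0])


def _single_pass(
    records, fps, sigma, test_fraction, seed
) -> tuple[list[int], list[int], int]:
    """Seeded random split + one transfer pass; returns index lists."""
    n = len(records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx = sorted(order[:n_test].tolist())
    train_idx = sorted(order[n_test:].tolist())
    if not test_idx:
        return train_idx, [], 0
    sims = _max_cross_tanimoto(fps[test_idx], fps[train_idx])
    keep = [i for i, s in zip(test_idx, sims) if s < sigma]
    moved = [i for i, s in zip(test_idx, sims) if s >= sigma]
    return sorted(train_idx + moved), keep, len(moved)


def tanimoto_transfer_split(corpus, config: SplitConfig) -> SplitResult:
    """Debiased split per the transfer rule, with bisection on the initial
    random fraction so the final test fraction hits the target.

    The transfer pass compares each test product against the full initial
    training side; transfers only ever grow the training set, so a single
    pass suffices.  If the target fraction cannot be reached within
    ``max_adjust_iterations`` the best split found is returned with
    ``converged=False``.
    """
    records = list(corpus)
    if len(records) < 2:
        raise ValueError("corpus must contain at least 2 reactions")
    fps = _fingerprint_matrix(records)
    target = config.target_test_fraction
    frac = (
        config.initial_test_fraction
        if config.initial_test_fraction is not None
        else target
    )

    lo, hi = 0.0, 1.0
    best = None
    frac0 = frac
    for _ in range(max(1, config.max_adjust_iterations)):
        train_idx, test_idx, moved = _single_pass(
            records, fps, config.sigma, frac, config.seed
        )
        achieved = len(test_idx) / len(records)
        if best is None or abs(achieved - target) < abs(best[3] - target):
            best = (train_idx, test_idx, moved, achieved, frac)
        if abs(achieved - target) <= config.fraction_tolerance:
            break
        # transferring only shrinks the test side, so achieved <= frac:
        # raise the initial fraction when short, lower it when over
        if achieved < target:
            lo = frac
        else:
            hi = frac
        if hi - lo < 1e-9:
            break
        frac = (lo + hi) / 2

    train_idx, test_idx, moved, achieved, used_frac = best
    if test_idx:
        max_cross = float(
            _max_cross_tanimoto(fps[test_idx], fps[train_idx]).max()
        )
    else:
        max_cross = 0.0
    return SplitResult(
        train_ids=[records[i].id for i in train_idx],
        test_ids=[records[i].id for i in test_idx],
        achieved_test_fraction=achieved,
        transferred_count=moved,
        max_cross_similarity=max_cross,
        sigma=config.sigma,
        converged=abs(achieved - target) <= config.fraction_tolerance,
        initial_test_fraction=used_frac,
    )


def overlap_fraction(train, test, sigma: float) -> float:
    """Fraction of test reactions whose first product has Tanimoto >= sigma
    to some training product (the quantity a random split inflates)."""
    test = list(test)
    train = list(train)
    if not test:
        raise ValueError("overlap_fraction is undefined for an empty test set")
    sims = _max_cross_tanimoto(
        _fingerprint_matrix(test), _fingerprint_matrix(train)
    )
    return float((sims >= sigma).mean())
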