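"""Integrated-gradients attribution of predicted product selectivity.

Given a reactant–reagent input and two candidate products, the quantity
being explained is the predicted probability difference

    dF(x) = F_major(x) - F_minor(x),

where ``F`` is the model's teacher-forced sequence probability and ``x``
the N x d source token-embedding matrix.  The attribution of token ``i``
is the path integral of the gradient of ``dF`` along the straight line
from a non-informative baseline ``x'`` to ``x``:

    IG_i = (x_i - x'_i) * integral_0^1  d dF(x' + a (x - x')) / d x_i  da,

discretized with a midpoint Riemann rule and summed over the d embedding
coordinates to give one number per token.  The baseline is the embedding
of the ``.`` separator token repeated N times: ``.`` only separates
molecules, so it carries no chemical information.

Token attributions are aggregated to chemically meaningful substructures
(reagent molecules, ring systems, branches) and compared against the
uniform attribution — the value each token would get if the probability
difference were spread evenly — which serves as the importance cutoff.
Positive attributions favour the major product, negative the minor one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .autodiff import Tensor
from .model import TransformerPredictor
from .reaction_io import TokenizedInput, canonicalize

__all__ = [
    "AttributionQuery",
    "AttributionResult",
    "SubstructureGrouping",
    "StructureError",
    "probability_difference",
    "integrated_gradients",
    "group_tokens",
    "aggregate",
    "uniform_attribution",
]


class StructureError(ValueError):
    """Unmatched parenthesis or dangling ring-closure digit."""


@dataclass(frozen=True)
class AttributionQuery:
    """One attribution request: a source and two candidate products."""

    source: TokenizedInput
    product_major: str
    product_minor: str
    steps: int = 50
    baseline_token: str = "."

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if canonicalize(self.product_major) == canonicalize(self.product_minor):
            raise ValueError("product_major and product_minor must differ")


@dataclass(frozen=True)
class SubstructureGrouping:
    """A partition of token indices into labeled substructure groups.

    Labels are ``reagent-molecule``, ``ring``, ``branch`` or ``atom/other``;
    every token index belongs to exactly one group.
    """

    groups: tuple[tuple[str, tuple[int, ...]], ...]
    n_tokens: int

    def __post_init__(self) -> None:
        covered = sorted(i for _, members in self.groups for i in members)
        if covered != list(range(self.n_tokens)):
            raise ValueError("groups do not partition the token index set")


@dataclass
class AttributionResult:
    """Token- and group-level integrated-gradients attributions."""

    delta_f: float                   # F_major - F_minor at the input
    delta_f_baseline: float          # same difference at the baseline
    token_attributions: np.ndarray   # per token, summed over embedding dims
    grouping: SubstructureGrouping
    group_attributions: np.ndarray
    uniform_per_token: float
    completeness_gap: float

    @property
    def span(self) -> float:
        """The quantity IG must account for: dF(x) - dF(x')."""
        return self.delta_f - self.delta_f_baseline

    def group_uniform_shares(self) -> np.ndarray:
        sizes = np.array([len(m) for _, m in self.grouping.groups], dtype=float)
        return sizes * self.uniform_per_token

    def important_groups(self) -> np.ndarray:
        """Boolean per group: |attribution| strictly above the uniform share."""
        return np.abs(self.group_attributions) > np.abs(self.group_uniform_shares())


def probability_difference(
    model: TransformerPredictor, source, product_major: str, product_minor: str
) -> float:
    """F(source -> major) - F(source -> minor); in [-1, 1]."""
    from .reaction_io import tokenize_smiles

    major = canonicalize(product_major)
    minor = canonicalize(product_minor)
    if major == minor:
        raise ValueError("products must differ")
    p_major = model.sequence_probability(source, tokenize_smiles(major).tokens)
    p_minor = model.sequence_probability(source, tokenize_smiles(minor).tokens)
    if p_major == 0.0 and p_minor == 0.0:
        warnings.warn(
            "both products have zero probability under the model; "
            "attribution of their difference is uninformative",
            stacklevel=2,
        )
    return p_major - p_minor


def _delta_f_tensor(model, emb: Tensor, major_tokens, minor_tokens) -> Tensor:
    return model.seq_prob_tensor(emb, major_tokens) - model.seq_prob_tensor(
        emb, minor_tokens
    )


def integrated_gradients(
    model: TransformerPredictor,
    query: AttributionQuery,
    grouping: SubstructureGrouping | None = None,
) -> AttributionResult:
    """Midpoint-rule integrated gradients for a probability difference.

    The attribution of every token sums over embedding coordinates; the
    completeness gap |sum_i IG_i - (dF(x) - dF(x'))| is recorded and
    shrinks as ``steps`` grows (it is exactly 0 for a linear model).
    """
    from .reaction_io import tokenize_smiles

    major = tokenize_smiles(canonicalize(query.product_major)).tokens
    minor = tokenize_smiles(canonicalize(query.product_minor)).tokens
    x = model.embed(query.source).astype(np.float64)
    xp = model.baseline_embedding(len(query.source), query.baseline_token).astype(
        np.float64
    )
    diff = x - xp

    total_grad = np.zeros_like(x)
    m = query.steps
    for k in range(m):
        alpha = (k + 0.5) / m
        point = Tensor(xp + alpha * diff, requires_grad=True)
        obj = _delta_f_tensor(model, point, major, minor)
        obj.backward()
        if not np.all(np.isfinite(point.grad)):
            raise FloatingPointError(
                f"non-finite gradient at path step {k} (alpha={alpha:.4f})"
            )
        total_grad += point.grad
    ig_matrix = diff * (total_grad / m)
    token_attr = ig_matrix.sum(axis=1)

    delta_f = float(_delta_f_tensor(model, Tensor(x), major, minor).data)
    delta_f_base = float(_delta_f_tensor(model, Tensor(xp), major, minor).data)
    span = delta_f - delta_f_base
    gap = abs(float(token_attr.sum()) - span)

    if grouping is None:
        grouping = group_tokens(query.source)
    group_attr = aggregate(token_attr, grouping)
    n = len(query.source)
    return AttributionResult(
        delta_f=delta_f,
        delta_f_baseline=delta_f_base,
        token_attributions=token_attr,
        grouping=grouping,
        group_attributions=group_attr,
        uniform_per_token=span / n,
        completeness_gap=gap,
    )


# ---------------------------------------------------------------------------
# substructure grouping


def _molecule_segments(tokens) -> list[tuple[int, list[int]]]:
    """Split token indices into molecule segments at top-level '.' tokens.

    Returns (dot_index_or_-1, member_indices) per molecule; the dot index
    is the separator immediately preceding the molecule.
    """
    segments: list[tuple[int, list[int]]] = []
    current: list[int] = []
    pending_dot = -1
    for i, tok in enumerate(tokens):
        if tok == ".":
            segments.append((pending_dot, current))
            pending_dot = i
            current = []
        else:
            current.append(i)
    segments.append((pending_dot, current))
    return segments


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Atom-index sets of ring systems (fused rings merged)."""
    systems: list[set[int]] = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            systems.remove(s)
            ring |= s
        systems.append(ring)
    return systems


_ATOM_TOKEN_FIRST = set("BCNOPSFIbcnops[")
_RING_BOND_FIRST = set("0123456789%")


def _is_atom_token(tok: str) -> bool:
    return tok[0] in _ATOM_TOKEN_FIRST or tok in ("Cl", "Br", "Si", "Se", "se")


def group_tokens(
    source: TokenizedInput, reagent_molecule_indices=()
) -> SubstructureGrouping:
    """Partition source tokens into substructure groups.

    Reagent molecules (identified by their position in the ``.``-split of
    the source, via ``reagent_molecule_indices``) are single groups, with
    the ``.`` separator preceding each reagent assigned to its group.
    Within reactants, each ring system (atom tokens plus their ring-closure
    digits) is one group; each outermost parenthesized branch hanging off a
    non-ring atom is one group (parentheses included); every remaining
    token is its own ``atom/other`` singleton.
    """
    tokens = source.tokens
    reagent_set = set(reagent_molecule_indices)
    segments = _molecule_segments(tokens)
    groups: list[tuple[str, tuple[int, ...]]] = []

    for mol_idx, (dot, members) in enumerate(segments):
        if not members:
            raise StructureError("empty molecule segment in source string")
        if mol_idx in reagent_set:
            grp = ([dot] if dot >= 0 else []) + members
            groups.append(("reagent-molecule", tuple(grp)))
            continue
        if dot >= 0:
            groups.append(("atom/other", (dot,)))  # separator between reactants

        smiles = "".join(tokens[i] for i in members)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureError(f"molecule segment {smiles!r} does not parse")
        # map atom tokens -> atom indices (SMILES order == RDKit atom order)
        atom_token_pos = [i for i in members if _is_atom_token(tokens[i])]
        if len(atom_token_pos) != mol.GetNumAtoms():
            raise StructureError(
                f"token/atom count mismatch in segment {smiles!r}"
            )
        atom_of_token = dict(zip(atom_token_pos, range(mol.GetNumAtoms())))
        ring_atoms_all: set[int] = set()
        systems = _ring_systems(mol)
        ring_atoms_all = set().union(*systems) if systems else set()
        sys_of_atom = {a: si for si, s in enumerate(systems) for a in s}

        assigned: set[int] = set()
        ring_groups: dict[int, list[int]] = {si: [] for si in range(len(systems))}

        # ring atoms and their ring-closure digits
        last_atom = None
        for i in members:
            tok = tokens[i]
            if _is_atom_token(tok):
                last_atom = atom_of_token[i]
                if last_atom in ring_atoms_all:
                    ring_groups[sys_of_atom[last_atom]].append(i)
                    assigned.add(i)
            elif tok[0] in _RING_BOND_FIRST:
                if last_atom is None:
                    raise StructureError(f"dangling ring closure at token {i}")
                if last_atom in ring_atoms_all:
                    ring_groups[sys_of_atom[last_atom]].append(i)
                    assigned.add(i)

        # outermost branches off non-ring atoms
        depth = 0
        branch_start = None
        branch_attach_ring = False
        last_atom = None
        for i in members:
            tok = tokens[i]
            if tok == "(":
                if depth == 0:
                    branch_start = i
                    branch_attach_ring = (
                        last_atom is not None and last_atom in ring_atoms_all
                    )
                depth += 1
            elif tok == ")":
                depth -= 1
                if depth < 0:
                    raise StructureError(f"unmatched ')' at token {i}")
                if depth == 0 and not branch_attach_ring:
                    span = [j for j in members if branch_start <= j <= i]
                    span = [j for j in span if j not in assigned]
                    if span:
                        groups.append(("branch", tuple(span)))
                        assigned.update(span)
            elif _is_atom_token(tok) and depth == 0:
                last_atom = atom_of_token[i]
        if depth != 0:
            raise StructureError("unmatched '(' in source string")

        for si, grp in ring_groups.items():
            if grp:
                groups.append(("ring", tuple(sorted(grp))))
        for i in members:
            if i not in assigned:
                groups.append(("atom/other", (i,)))

    ordered = sorted(groups, key=lambda g: g[1][0])
    return SubstructureGrouping(groups=tuple(ordered), n_tokens=len(tokens))


def aggregate(token_attributions, grouping: SubstructureGrouping) -> np.ndarray:
    """Sum token attributions within each group; conserves the total."""
    attr = np.asarray(token_attributions, dtype=float)
    if attr.shape[0] != grouping.n_tokens:
        raise IndexError(
            f"{attr.shape[0]} attributions for {grouping.n_tokens} tokens"
        )
    return np.array(
        [sum(attr[i] for i in members) for _, members in grouping.groups]
    )


def uniform_attribution(
    delta_f_at_input: float,
    delta_f_at_baseline: float,
    grouping: SubstructureGrouping,
) -> tuple[float, np.ndarray]:
    """The even spread of the probability-difference span over tokens.

    Returns (per-token uniform value, per-group uniform values); a group's
    share is its token count times the per-token value.
    """
    n = grouping.n_tokens
    per_token = (delta_f_at_input - delta_f_at_baseline) / n
    sizes = np.array([len(m) for _, m in grouping.groups], dtype=float)
    return per_token, sizes * per_token
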