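"""Synthetic Friedel–Crafts acylation benchmark generator.

Electrophilic aromatic substitution on a singly substituted benzene is
regioselective: the ring substituent directs the incoming acyl group to
the para (1,4) or meta (1,3) position.  This module enumerates such
reactions from SMARTS reaction templates — ten para-directing and ten
meta-directing benzene derivatives reacting with acyl chlorides built
from straight carbon chains — and assembles training corpora with a
controlled para:meta ratio (Balanced 1:1, Biased 9:1, Severely Biased
100:1) plus a fixed balanced test set whose acyl chlorides (chains of
length 9–10) are disjoint from every training acyl chloride (chains of
length 2–8).

Because every reaction is labeled with the orientation its template
requested, and :func:`classify_orientation` recovers that label from the
product alone by an independent substructure-query route, the generator
is self-validating: every corpus is checked label-by-label on build.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .reaction_io import ReactionRecord, canonicalize, write_corpus

__all__ = [
    "PARA_BENZYLS",
    "META_BENZYLS",
    "TEST_PARA_BENZYLS",
    "TEST_META_BENZYLS",
    "BiasDatasetSpec",
    "LabeledReaction",
    "GenerationError",
    "enumerate_r_groups",
    "make_acyl_chlorides",
    "generate_fc_reaction",
    "classify_orientation",
    "build_datasets",
    "write_datasets",
]


class GenerationError(ValueError):
    """Template application or dataset-ratio construction failed."""


# The twenty singly substituted benzenes, as (name, canonical SMILES).
PARA_BENZYLS: dict[str, str] = {
    "fluorobenzene": "Fc1ccccc1",
    "chlorobenzene": "Clc1ccccc1",
    "isopropylbenzene": "CC(C)c1ccccc1",
    "tert-butylbenzene": "CC(C)(C)c1ccccc1",
    "N-phenylacetamide": "CC(=O)Nc1ccccc1",
    "N-phenylpropionamide": "CCC(=O)Nc1ccccc1",
    "phenol": "Oc1ccccc1",
    "ethoxybenzene": "CCOc1ccccc1",
    "isopropoxybenzene": "CC(C)Oc1ccccc1",
    "sec-butylbenzene": "CCC(C)c1ccccc1",
}
META_BENZYLS: dict[str, str] = {
    "N,N,N-trimethylbenzenaminium": "C[N+](C)(C)c1ccccc1",
    "(trifluoromethyl)benzene": "FC(F)(F)c1ccccc1",
    "benzaldehyde": "O=Cc1ccccc1",
    "acetophenone": "CC(=O)c1ccccc1",
    "methyl benzoate": "COC(=O)c1ccccc1",
    "ethyl benzoate": "CCOC(=O)c1ccccc1",
    "benzonitrile": "N#Cc1ccccc1",
    "nitrobenzene": "O=[N+]([O-])c1ccccc1",
    "methyl benzenesulfonate": "COS(=O)(=O)c1ccccc1",
    "ethyl benzenesulfonate": "CCOS(=O)(=O)c1ccccc1",
}
# The fixed test set uses three benzyls of each kind.
TEST_META_BENZYLS = ("benzaldehyde", "(trifluoromethyl)benzene", "nitrobenzene")
TEST_PARA_BENZYLS = ("fluorobenzene", "N-phenylpropionamide", "ethoxybenzene")


@dataclass(frozen=True)
class BiasDatasetSpec:
    """Conditions for one artificial training corpus.

    ``acyl_split_ratio`` is the para:meta reaction ratio the corpus must
    hit exactly (1:1 balanced, 9:1 biased, 100:1 severely biased); it is
    realized by a seeded split of the acyl-chloride pool.
    """

    name: str
    para_benzyls: tuple[str, ...] = tuple(PARA_BENZYLS)
    meta_benzyls: tuple[str, ...] = tuple(META_BENZYLS)
    r_group_lengths: tuple[int, int] = (2, 8)
    r_group_max_double_bonds: int = 1
    acyl_split_ratio: Fraction = Fraction(1, 1)
    placement: str = "exhaustive"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.para_benzyls or not self.meta_benzyls:
            raise ValueError("benzyl lists must be non-empty")
        if self.r_group_lengths[0] < 2:
            raise ValueError("chain lengths must be >= 2")
        if self.placement not in ("exhaustive", "random"):
            raise ValueError(f"unknown placement mode {self.placement!r}")


BALANCED = BiasDatasetSpec(name="balanced", acyl_split_ratio=Fraction(1, 1))
BIASED = BiasDatasetSpec(name="biased", acyl_split_ratio=Fraction(9, 1))
SEVERE = BiasDatasetSpec(
    name="severe",
    meta_benzyls=TEST_META_BENZYLS,
    acyl_split_ratio=Fraction(100, 1),
)
PRESETS = {"balanced": BALANCED, "biased": BIASED, "severe": SEVERE}


@dataclass
class LabeledReaction:
    """A generated reaction with its requested orientation label."""

    record: ReactionRecord
    orientation: str  # "para" | "meta"
    benzyl_id: str
    acyl_id: str


def enumerate_r_groups(lengths=(2, 8), max_double_bonds: int = 1) -> list[str]:
    """All straight (unbranched) carbon chains of the given length range
    with 0..``max_double_bonds`` C=C double bonds, canonical and deduplicated,
    in deterministic (length, SMILES) order."""
    lo, hi = lengths
    seen: dict[str, tuple[int, str]] = {}
    for n in range(lo, hi + 1):
        chains = ["C" * n]
        if max_double_bonds >= 1:
            for b in range(1, n):  # double bond between carbons b and b+1
                chains.append("C" * b + "=" + "C" * (n - b))
        for smi in chains:
            can = canonicalize(smi)
            seen.setdefault(can, (n, can))
    return [smi for _, smi in sorted(seen.values())]


def _sp3_carbons(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetHybridization() == Chem.HybridizationType.SP3
    ]


_ACYL_FRAGMENT = "C(=O)Cl"


def _attach_acyl(r_mol: Chem.Mol, atom_idx: int) -> str:
    frag = Chem.MolFromSmiles(_ACYL_FRAGMENT)
    combo = Chem.RWMol(Chem.CombineMols(r_mol, frag))
    carbonyl = r_mol.GetNumAtoms()  # first atom of the fragment
    combo.AddBond(atom_idx, carbonyl, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def make_acyl_chlorides(
    r_groups, seed: int = 0, placement: str = "random"
) -> list[str]:
    """Acyl chlorides from R groups by C(=O)Cl placement on sp3 carbons.

    ``random``: one seeded-random sp3 carbon per R group (R groups with no
    sp3 carbon are skipped).  ``exhaustive``: every symmetry-distinct sp3
    position.  Output is canonical, deduplicated and deterministically
    ordered.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[int, str]] = {}
    for r in r_groups:
        mol = Chem.MolFromSmiles(r)
        if mol is None:
            raise GenerationError(f"R group {r!r} does not parse")
        sp3 = _sp3_carbons(mol)
        if not sp3:
            continue  # e.g. ethylene: no sp3 carbon to acylate
        if placement == "random":
            positions = [int(rng.choice(sp3))]
        elif placement == "exhaustive":
            positions = sp3
        else:
            raise ValueError(f"unknown placement mode {placement!r}")
        for pos in positions:
            smi = _attach_acyl(mol, pos)
            m = Chem.MolFromSmiles(smi)
            out.setdefault(smi, (m.GetNumAtoms(), smi))
    if not out:
        raise GenerationError("no acyl chlorides could be generated")
    return [smi for _, smi in sorted(out.values())]


# Reaction SMARTS: a singly substituted benzene (ipso carbon has no H,
# all other ring positions do) + an acyl chloride -> acylated ring.  The
# para template installs the acyl group 1,4 to the ipso carbon, the meta
# template 1,3.
_RXN_SMARTS = {
    "para": (
        "[c;H0:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[#6:7][C:8](=[O:9])Cl>>"
        "[c:1]1[cH:2][cH:3][c:4](-[C:8](=[O:9])[#6:7])[cH:5][cH:6]1"
    ),
    "meta": (
        "[c;H0:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[#6:7][C:8](=[O:9])Cl>>"
        "[c:1]1[cH:2][c:3](-[C:8](=[O:9])[#6:7])[cH:4][cH:5][cH:6]1"
    ),
}
_REACTIONS = {k: AllChem.ReactionFromSmarts(v) for k, v in _RXN_SMARTS.items()}

_ACYL_CHLORIDE_QUERY = Chem.MolFromSmarts("[#6][CX3](=O)Cl")


def generate_fc_reaction(
    benzyl: str, acyl_chloride: str, orientation: str,
    benzyl_id: str = "", acyl_id: str = "",
) -> LabeledReaction:
    """Apply the para or meta acylation template to one reactant pair."""
    if orientation not in _REACTIONS:
        raise ValueError(f"orientation must be 'para' or 'meta', got {orientation!r}")
    bmol = Chem.MolFromSmiles(benzyl)
    amol = Chem.MolFromSmiles(acyl_chloride)
    if bmol is None or amol is None:
        raise GenerationError(f"reactant does not parse: {benzyl!r} / {acyl_chloride!r}")
    if len(amol.GetSubstructMatches(_ACYL_CHLORIDE_QUERY)) != 1:
        raise GenerationError(
            f"{acyl_chloride!r} must contain exactly one C(=O)Cl group"
        )
    products = set()
    for prod_set in _REACTIONS[orientation].RunReactants((bmol, amol)):
        mol = prod_set[0]
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        products.add(Chem.MolToSmiles(mol))
    if len(products) != 1:
        raise GenerationError(
            f"{orientation} template gave {len(products)} distinct products for "
            f"{benzyl!r} + {acyl_chloride!r}"
        )
    product = products.pop()
    record = ReactionRecord(
        id=f"fc-{orientation}-{benzyl_id or benzyl}-{acyl_id or acyl_chloride}",
        reactants=[canonicalize(benzyl), canonicalize(acyl_chloride)],
        reagents=[],
        products=[product],
    )
    return LabeledReaction(
        record=record, orientation=orientation,
        benzyl_id=benzyl_id or benzyl, acyl_id=acyl_id or acyl_chloride,
    )


def _substituted_queries(benzyl: str) -> dict[str, Chem.Mol]:
    """For one benzyl, product query molecules with a generic acyl stub
    (C(=O)C) attached ortho / meta / para to the directing group."""
    bmol = Chem.MolFromSmiles(benzyl)
    ring = None
    for r in bmol.GetRingInfo().AtomRings():
        if len(r) == 6 and all(
            bmol.GetAtomWithIdx(i).GetIsAromatic()
            and bmol.GetAtomWithIdx(i).GetSymbol() == "C"
            for i in r
        ):
            ring = list(r)
            break
    if ring is None:
        raise GenerationError(f"{benzyl!r} has no benzene ring")
    ipso = [
        i
        for i in ring
        if any(n.GetIdx() not in ring for n in bmol.GetAtomWithIdx(i).GetNeighbors())
    ]
    if len(ipso) != 1:
        raise GenerationError(f"{benzyl!r} is not singly substituted")
    # order ring atoms by graph walk from ipso
    pos = [ipso[0]]
    while len(pos) < 6:
        nxt = [
            n.GetIdx()
            for n in bmol.GetAtomWithIdx(pos[-1]).GetNeighbors()
            if n.GetIdx() in ring and n.GetIdx() not in pos
        ]
        pos.append(nxt[0])
    offsets = {"ortho": 1, "meta": 2, "para": 3}
    stub = Chem.MolFromSmiles("C(C)=O")  # acyl stub: ring-C(=O)-C; atom 0 is the carbonyl C
    queries = {}
    for label, off in offsets.items():
        combo = Chem.RWMol(Chem.CombineMols(bmol, stub))
        carbonyl = bmol.GetNumAtoms()  # first stub atom = the carbonyl carbon
        combo.AddBond(pos[off], carbonyl, Chem.BondType.SINGLE)
        q = combo.GetMol()
        Chem.SanitizeMol(q)
        queries[label] = q
    return queries


_QUERY_CACHE: dict[str, dict[str, Chem.Mol]] = {}


def classify_orientation(product: str, benzyl: str) -> str:
    """Classify a (possibly model-decoded) product string.

    Returns ``invalid`` when the string does not parse, ``para`` / ``meta``
    / ``ortho`` when the product contains the directing-group benzene ring
    with an acyl substituent in the corresponding relative position, and
    ``other`` otherwise.  Total function: never raises on bad input.
    """
    mol = Chem.MolFromSmiles(product) if product else None
    if mol is None:
        return "invalid"
    if benzyl not in _QUERY_CACHE:
        _QUERY_CACHE[benzyl] = _substituted_queries(benzyl)
    for label in ("para", "meta", "ortho"):
        if mol.HasSubstructMatch(_QUERY_CACHE[benzyl][label]):
            return label
    return "other"


def _enumerate_pairs(benzyls: dict[str, str], names, acyls, orientation):
    out = []
    for name in names:
        for j, acyl in enumerate(acyls):
            rxn = generate_fc_reaction(
                benzyls[name], acyl, orientation,
                benzyl_id=name, acyl_id=f"a{j}",
            )
            got = classify_orientation(rxn.record.products[0], benzyls[name])
            if got != orientation:
                raise GenerationError(
                    f"self-consistency failure: requested {orientation}, "
                    f"classified {got} for {name} + {acyl}"
                )
            out.append(rxn)
    return out


def _ratio_split(acyls: list[str], ratio: Fraction, rng) -> tuple[list[str], list[str]]:
    """Seeded split of the acyl pool into (para-side, meta-side) subsets."""
    p, m = ratio.numerator, ratio.denominator
    return _ratio_split_weighted(acyls, p, m, rng)


def _ratio_split_weighted(acyls, wp, wm, rng):
    k = len(acyls) // (wp + wm)
    if k < 1:
        raise GenerationError(
            f"cannot realize ratio {wp}:{wm} from {len(acyls)} acyl chlorides"
        )
    order = rng.permutation(len(acyls))
    take = order[: k * (wp + wm)]
    para = [acyls[i] for i in sorted(take[: k * wp])]
    meta = [acyls[i] for i in sorted(take[k * wp :])]
    return para, meta


def build_datasets(spec: BiasDatasetSpec) -> tuple[list[LabeledReaction], list[LabeledReaction]]:
    """Build (train, test) labeled corpora for one bias condition.

    The training corpus hits the spec's para:meta ratio exactly: the acyl
    pool (straight chains, lengths per spec, acylated per the placement
    mode) is split by seeded choice into a para-side and a meta-side subset
    whose reaction counts realize the ratio; surplus acyl chlorides that
    would break exactness are dropped.  The test corpus is always balanced:
    three named para and three named meta benzyls with saturated chains of
    length 9–10, so no test acyl chloride occurs in any training corpus.
    """
    rng = np.random.default_rng(spec.seed)
    r_groups = enumerate_r_groups(spec.r_group_lengths, spec.r_group_max_double_bonds)
    acyls = make_acyl_chlorides(r_groups, seed=spec.seed, placement=spec.placement)

    n_pb, n_mb = len(spec.para_benzyls), len(spec.meta_benzyls)
    ratio = spec.acyl_split_ratio
    if ratio == 1 and n_pb == n_mb:
        para_acyls = meta_acyls = acyls
    else:
        # reaction counts are acyl counts x benzyl counts; solve for integer
        # acyl weights realizing the reaction ratio exactly
        want = Fraction(ratio.numerator * n_mb, ratio.denominator * n_pb)
        para_acyls, meta_acyls = _ratio_split_weighted(
            acyls, want.numerator, want.denominator, rng
        )
    train = _enumerate_pairs(PARA_BENZYLS, spec.para_benzyls, para_acyls, "para")
    train += _enumerate_pairs(
        {**PARA_BENZYLS, **META_BENZYLS}, spec.meta_benzyls, meta_acyls, "meta"
    )
    n_para = sum(r.orientation == "para" for r in train)
    n_meta = len(train) - n_para
    if Fraction(n_para, n_meta) != ratio:
        raise GenerationError(
            f"achieved para:meta {n_para}:{n_meta} does not realize {ratio}"
        )

    test_r = enumerate_r_groups((9, 10), 0)
    test_acyls = make_acyl_chlorides(test_r, seed=spec.seed, placement=spec.placement)
    test = _enumerate_pairs(PARA_BENZYLS, TEST_PARA_BENZYLS, test_acyls, "para")
    test += _enumerate_pairs(META_BENZYLS, TEST_META_BENZYLS, test_acyls, "meta")
    return train, test


def counts(reactions) -> dict[str, int]:
    out = {"para": 0, "meta": 0}
    for r in reactions:
        out[r.orientation] = out.get(r.orientation, 0) + 1
    return out


def write_datasets(spec: BiasDatasetSpec, out_dir) -> dict:
    """Write train/test corpora in both dialects plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train, test = build_datasets(spec)
    manifest = {
        "name": spec.name,
        "seed": spec.seed,
        "placement": spec.placement,
        "ratio": f"{spec.acyl_split_ratio.numerator}:{spec.acyl_split_ratio.denominator}",
        "train_counts": counts(train),
        "test_counts": counts(test),
    }
    for tag, rxns in (("train", train), ("test", test)):
        records = [r.record for r in rxns]
        write_corpus(records, out_dir / f"{tag}.txt", dialect="reaction-line")
        write_corpus(records, out_dir / f"{tag}", dialect="src-tgt")
        with open(out_dir / f"{tag}.labels.json", "w") as fh:
            json.dump(
                [
                    {"id": r.record.id, "orientation": r.orientation,
                     "benzyl_id": r.benzyl_id, "acyl_id": r.acyl_id}
                    for r in rxns
                ],
                fh,
            )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
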