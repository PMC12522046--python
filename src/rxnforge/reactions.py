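"""Reaction SMILES sources feeding the image generator.

The generator only needs valid reaction SMILES (``reactants>agents>products``).
Two sources are provided: a file of one reaction per line, and a bundled toy
source combining a curated list of common small-molecule transformations with
a combinatorial generator (functional-group transforms applied to random
alkyl/aryl scaffolds).  The toy source can also emit *branch groups* (several
reactions sharing one reactant set) and *chain nodes* (a molecule sequence
for closed catalytic-cycle layouts), which the branch and cycle patterns
require.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Protocol

from rdkit import Chem

from .rng import RNGStream
from .scheme import ReactionParseError, split_reaction_smiles


@dataclass(frozen=True)
class ReactionInput:
    """A parsed reaction: molecule SMILES per field plus the raw source string."""

    reactants: tuple[str, ...]
    agents: tuple[str, ...]
    products: tuple[str, ...]
    raw: str


def parse_reaction_smiles(reaction: str) -> ReactionInput:
    r, a, p = split_reaction_smiles(reaction)
    if not r or not p:
        raise ReactionParseError(f"reaction needs >=1 reactant and product: {reaction!r}")
    for m in (*r, *a, *p):
        if Chem.MolFromSmiles(m) is None:
            raise ReactionParseError(f"molecule {m!r} in {reaction!r} does not parse")
    return ReactionInput(tuple(r), tuple(a), tuple(p), reaction)


# --------------------------------------------------------------------------
# curated toy reactions (all verified parseable by the test suite)

CURATED_REACTIONS: tuple[str, ...] = (
    "CCO.CC(=O)O>[H+]>CCOC(C)=O",
    "CCO>>CC=O",
    "CC=O>[BH4-]>CCO",
    "CC(=O)c1ccccc1>>CC(O)c1ccccc1",
    "Brc1ccccc1.OB(O)c1ccccc1>>c1ccc(-c2ccccc2)cc1",
    "CC(=O)O.CN>>CNC(C)=O",
    "C=CC>[H][H]>CCC",
    "O=[N+]([O-])c1ccccc1>[H][H]>Nc1ccccc1",
    "CCBr.[N-]=[N+]=[N-]>>CCN=[N+]=[N-]",
    "CCCl.CCO>>CCOCC",
    "CC(C)=O.NCC>>CC(C)NCC",
    "O=Cc1ccccc1.CC(C)=O>>CC(=O)C=Cc1ccccc1",
    "CC(=O)Cl.OCC>>CCOC(C)=O",
    "c1ccccc1.CC(=O)Cl>Cl[Al](Cl)Cl>CC(=O)c1ccccc1",
    "C=CC=C.C=C>>C1=CCCCC1",
    "CCO>>CC(=O)O",
    "CC#N>[H][H]>CCN",
    "Brc1ccccc1>>N#Cc1ccccc1",
    "COC(C)=O>O>CC(=O)O.CO",
    "CC=O.C[Mg]Br>>CC(C)O",
    "C=CC>OO>CC1CO1",
    "Oc1ccccc1.CI>>COc1ccccc1",
    "CCN.CC(=O)OC(C)=O>>CCNC(C)=O",
    "O=Cc1ccccc1.C=P(c1ccccc1)(c1ccccc1)c1ccccc1>>C=Cc1ccccc1",
    "c1ccccc1>BrBr>Brc1ccccc1",
    "CC(C)O>>CC(C)=O",
    "CCCO>>CCC=O",
    "CCC=O>>CCC(=O)O",
    "OCCO.CC(C)=O>[H+]>CC1(C)OCCO1",
    "CCCCBr.[C-]#N>>CCCCC#N",
    "CC(Br)CC>>CC=CC",
    "O=Cc1ccccc1.NO>>ON=Cc1ccccc1",
    "CCOC(=O)CC(=O)OCC.CCBr>>CCOC(=O)C(CC)C(=O)OCC",
    "Clc1ccccc1.CN>>CNc1ccccc1",
    "CC(=O)CC(C)=O.NO>>CC1=CC(=NO1)C",
    "OC(=O)c1ccccc1.CO>[H+]>COC(=O)c1ccccc1",
    "C1CCCCC1=O>[BH4-]>OC1CCCCC1",
    "CC(N)C(=O)O.CC(=O)Cl>>CC(NC(C)=O)C(=O)O",
    "Ic1ccccc1.C#Cc1ccccc1>>c1ccc(C#Cc2ccccc2)cc1",
    "CC=CC>OO>CC1OC1C",
)


# --------------------------------------------------------------------------
# combinatorial generator


def _alkyl(g, n_min: int = 1, n_max: int = 5) -> str:
    return "C" * int(g.integers(n_min, n_max + 1))


_SMILES_AGENT_POOL = ("[H+]", "O", "[BH4-]", "[H][H]", "OS(=O)(=O)O")


class ToyReactionSource:
    """Bundled reaction source: curated transformations + scaffold transforms."""

    def __init__(self, curated: Optional[tuple[str, ...]] = None, p_curated: float = 0.5):
        self.curated = curated if curated is not None else CURATED_REACTIONS
        self.p_curated = p_curated

    # ---- single reactions

    def draw(self, rng: RNGStream) -> str:
        g = rng.generator()
        if self.curated and g.random() < self.p_curated:
            return self.curated[int(g.integers(len(self.curated)))]
        return self._synthesize(g)

    def _synthesize(self, g) -> str:
        r = _alkyl(g)
        kind = int(g.integers(6))
        agents = ""
        if g.random() < 0.4:
            agents = _SMILES_AGENT_POOL[int(g.integers(len(_SMILES_AGENT_POOL)))]
        if kind == 0:  # primary alcohol -> aldehyde
            rxn = f"{r}CO>{agents}>{r}C=O"
        elif kind == 1:  # aldehyde -> carboxylic acid
            rxn = f"{r}C=O>{agents}>{r}C(=O)O"
        elif kind == 2:  # Fischer esterification
            r2 = _alkyl(g)
            rxn = f"{r}CO.{r2}C(=O)O>[H+]>{r2}C(=O)OC{r}"
        elif kind == 3:  # alkyl bromide + amine
            r2 = _alkyl(g)
            rxn = f"{r}CBr.{r2}N>{agents}>{r}CN{r2}"
        elif kind == 4:  # para-substituted aryl bromide Suzuki coupling
            rxn = f"Brc1ccc({r})cc1.OB(O)c1ccccc1>{agents}>c1ccc(-c2ccc({r})cc2)cc1"
        else:  # nitroarene reduction
            rxn = f"O=[N+]([O-])c1ccc({r})cc1>[H][H]>Nc1ccc({r})cc1"
        return rxn

    # ---- branch groups: k reactions sharing one reactant set

    def draw_group(self, rng: RNGStream, k: int) -> list[str]:
        g = rng.generator()
        r = _alkyl(g, 2, 5)
        alcohol = f"{r}CO"
        arms = [
            f"{alcohol}>>{r}C=O",                      # oxidation to aldehyde
            f"{alcohol}>>{r}C(=O)O",                   # oxidation to acid
            f"{alcohol}>[H+]>C=C{'C' * (len(r) - 1)}",  # dehydration to alkene
            f"{alcohol}>>{r}CBr",                      # bromination
            f"{alcohol}>>{r}COC(C)=O",                 # acetylation
        ]
        order = g.permutation(len(arms))
        return [arms[int(i)] for i in order[: max(2, min(k, len(arms)))]]

    # ---- chain nodes: molecules for a closed cycle layout

    def draw_chain_nodes(self, rng: RNGStream, k: int) -> list[str]:
        g = rng.generator()
        r = _alkyl(g, 2, 4)
        derivatives = [
            f"{r}CO", f"{r}C=O", f"{r}C(=O)O", f"{r}C(=O)OC",
            f"{r}CBr", f"{r}CN", f"{r}C(=O)N",
        ]
        order = g.permutation(len(derivatives))
        return [derivatives[int(i)] for i in order[:k]]


class FileReactionSource:
    """One reaction SMILES per line; '#' comments and blank lines ignored."""

    def __init__(self, path: str):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        with open(path) as fh:
            lines = [ln.strip() for ln in fh]
        self.reactions = [ln for ln in lines if ln and not ln.startswith("#")]
        if not self.reactions:
            raise ReactionParseError(f"no reactions found in {path}")

    def draw(self, rng: RNGStream) -> str:
        g = rng.generator()
        return self.reactions[int(g.integers(len(self.reactions)))]

    def draw_group(self, rng: RNGStream, k: int) -> list[str]:
        # prefer genuine shared-reactant groups from the file
        groups: dict[str, list[str]] = {}
        for rxn in self.reactions:
            try:
                r, _, _ = split_reaction_smiles(rxn)
            except ReactionParseError:
                continue
            groups.setdefault(".".join(sorted(r)), []).append(rxn)
        big = [v for v in groups.values() if len(v) >= 2]
        g = rng.generator()
        if big:
            grp = big[int(g.integers(len(big)))]
            return grp[: max(2, k)]
        # fallback: derive arms that share the first reaction's reactant set
        base = parse_reaction_smiles(self.draw(rng))
        arms = [base.raw]
        for _ in range(max(2, k) - 1):
            other = parse_reaction_smiles(self.draw(rng))
            arms.append(
                ">".join(
                    (".".join(base.reactants), ".".join(other.agents), ".".join(other.products))
                )
            )
        return arms

    def draw_chain_nodes(self, rng: RNGStream, k: int) -> list[str]:
        g = rng.generator()
        nodes: list[str] = []
        seen: set[str] = set()
        guard = 0
        while len(nodes) < k and guard < 50 * k:
            guard += 1
            try:
                ri = parse_reaction_smiles(self.draw(rng))
            except ReactionParseError:
                continue
            for m in (*ri.reactants, *ri.products):
                if m not in seen:
                    seen.add(m)
                    nodes.append(m)
                if len(nodes) >= k:
                    break
        if len(nodes) < k:
            raise ReactionParseError(f"could not collect {k} distinct molecules for a cycle")
        return nodes


class ReactionSourceLike(Protocol):
    def draw(self, rng: RNGStream) -> str: ...
    def draw_group(self, rng: RNGStream, k: int) -> list[str]: ...
    def draw_chain_nodes(self, rng: RNGStream, k: int) -> list[str]: ...
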