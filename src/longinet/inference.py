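"""Substructure-drug-target network-based inference (bSDTNBI-style).

New targets for a compound are prioritized by resource diffusion on a
tripartite network joining drugs to their known targets (D-T edges) and to
their substructure fingerprint keys (D-S edges). Four parameters control
the diffusion: ``alpha`` splits the query drug's initial resource between
its target and substructure neighbors, ``beta`` splits each drug's
outgoing mass between the two edge classes, ``gamma`` damps the influence
of hub recipients (each transfer is scaled by deg(recipient)**gamma), and
``k`` is the number of diffusion steps. After an even number of steps from
a drug start the resource sits on targets and substructures; target nodes
not already linked to the query drug are ranked by their final resource,
and the top ``top_n`` become predicted interactions.

At ``gamma = 0`` the transfer matrix is column-stochastic and total
resource is conserved exactly; ``gamma < 0`` (default -0.5) deliberately
bleeds resource away from hubs and the total is no longer conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from rdkit import Chem

from .network import DTINetwork

#: Compact built-in SMARTS dictionary standing in for a full substructure
#: fingerprint set (e.g. the Klekota-Roth dictionary). Keys are matched as
#: substructure queries; any user dictionary with the same (key, SMARTS)
#: shape can replace it.
DEFAULT_SMARTS_DICTIONARY: dict[str, str] = {
    "aromatic_6_ring": "c1ccccc1",
    "aromatic_5_ring": "[a;r5]1[a;r5][a;r5][a;r5][a;r5]1",
    "phenol": "c[OX2H]",
    "aniline": "c[NX3;H2,H1]",
    "benzene_fused": "c1ccc2ccccc2c1",
    "pyridine": "n1ccccc1",
    "pyrrole_like": "[nH]1cccc1",
    "imidazole": "c1cnc[nH]1",
    "furan": "o1cccc1",
    "thiophene": "s1cccc1",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "carboxylate": "[CX3](=O)[O-]",
    "ester": "[CX3](=O)[OX2][#6]",
    "amide": "[CX3](=O)[NX3]",
    "ketone": "[#6][CX3](=O)[#6]",
    "aldehyde": "[CX3H1]=O",
    "primary_amine": "[NX3;H2][#6]",
    "secondary_amine": "[NX3;H1]([#6])[#6]",
    "tertiary_amine": "[NX3]([#6])([#6])[#6]",
    "quaternary_n": "[NX4+]",
    "guanidine": "[NX3][CX3](=[NX2])[NX3]",
    "nitro": "[NX3](=O)=O",
    "nitrile": "[CX2]#N",
    "hydroxyl": "[OX2H]",
    "ether": "[OD2]([#6])[#6]",
    "thiol": "[SX2H]",
    "thioether": "[SX2]([#6])[#6]",
    "sulfonamide": "[SX4](=O)(=O)[NX3]",
    "sulfone": "[SX4](=O)(=O)[#6]",
    "halogen_f": "[F]",
    "halogen_cl": "[Cl]",
    "halogen_br": "[Br]",
    "halogen_i": "[I]",
    "alkene": "[CX3]=[CX3]",
    "alkyne": "[CX2]#[CX2]",
    "methyl": "[CH3]",
    "gem_dimethyl": "[CX4]([CH3])([CH3])",
    "isopropyl": "[CH](C)(C)",
    "cyclopropane": "C1CC1",
    "cyclohexane": "C1CCCCC1",
    "lactone": "[CX3](=O)[OX2][#6;R]",
    "lactam": "[CX3](=O)[NX3][#6;R]",
    "urea": "[NX3][CX3](=O)[NX3]",
    "carbamate": "[NX3][CX3](=O)[OX2]",
    "phosphate": "[PX4](=O)([OX2])([OX2])",
    "enol_ether": "[CX3]=[CX3][OX2]",
    "conjugated_carbonyl": "[CX3]=[CX3][CX3]=O",
    "catechol": "c1cc(O)c(O)cc1",
    "methoxy_aromatic": "c[OX2][CH3]",
    "benzylic_carbon": "[CX4]c",
    "trifluoromethyl": "[CX4](F)(F)F",
}


@dataclass(frozen=True)
class SubstructureProfile:
    """Substructure fingerprint keys present in one compound."""

    compound_id: str
    keys: frozenset[str]

    @property
    def empty(self) -> bool:
        return not self.keys


def compute_substructure_profile(
    smiles: str,
    dictionary: Mapping[str, str] | None = None,
    compound_id: str | None = None,
) -> SubstructureProfile:
    """Match a structure against a named SMARTS dictionary."""
    if dictionary is None:
        dictionary = DEFAULT_SMARTS_DICTIONARY
    mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    keys = set()
    for key, smarts in dictionary.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for key {key!r}: {smarts!r}")
        if mol.HasSubstructMatch(patt):
            keys.add(key)
    return SubstructureProfile(compound_id or str(smiles), frozenset(keys))


@dataclass(frozen=True)
class InferenceParams:
    """Diffusion parameters; defaults follow the published setting."""

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = -0.5
    k: int = 2
    top_n: int = 20
    #: which neighbor class receives the alpha/beta (minority) share
    alpha_to: str = "substructures"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.k % 2 != 0:
            raise ValueError(
                "k must be even: odd step counts leave resource on drug nodes"
            )
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.alpha_to not in ("substructures", "targets"):
            raise ValueError("alpha_to must be 'substructures' or 'targets'")


class TripartiteNetwork:
    """Substructure-drug-target graph used for resource diffusion.

    Nodes are ordered drugs, then targets, then substructures; resource
    vectors and the transfer matrix share this ordering.
    """

    def __init__(
        self,
        drug_targets: Mapping[str, Iterable[str]],
        drug_subs: Mapping[str, Iterable[str]],
    ) -> None:
        self.drugs: list[str] = sorted(drug_targets)
        targets: set[str] = set()
        for ts in drug_targets.values():
            targets |= set(ts)
        self.targets: list[str] = sorted(targets)
        subs: set[str] = set()
        for ss in drug_subs.values():
            subs |= set(ss)
        self.subs: list[str] = sorted(subs)  # zero-drug keys never enter

        self.drug_targets = {d: frozenset(drug_targets[d]) for d in self.drugs}
        self.drug_subs = {
            d: frozenset(drug_subs.get(d, ())) for d in self.drugs
        }
        self.target_drugs: dict[str, set[str]] = {t: set() for t in self.targets}
        self.sub_drugs: dict[str, set[str]] = {s: set() for s in self.subs}
        for d in self.drugs:
            for t in self.drug_targets[d]:
                self.target_drugs[t].add(d)
            for s in self.drug_subs[d]:
                self.sub_drugs[s].add(d)

        self._index = {("drug", d): i for i, d in enumerate(self.drugs)}
        off = len(self.drugs)
        self._index.update(
            {("target", t): off + i for i, t in enumerate(self.targets)}
        )
        off += len(self.targets)
        self._index.update({("sub", s): off + i for i, s in enumerate(self.subs)})

    @property
    def n_nodes(self) -> int:
        return len(self.drugs) + len(self.targets) + len(self.subs)

    def index(self, kind: str, name: str) -> int:
        return self._index[(kind, name)]

    def degree(self, kind: str, name: str) -> int:
        if kind == "drug":
            return len(self.drug_targets[name]) + len(self.drug_subs[name])
        if kind == "target":
            return len(self.target_drugs[name])
        if kind == "sub":
            return len(self.sub_drugs[name])
        raise ValueError(kind)

    @property
    def n_dt_edges(self) -> int:
        return sum(len(v) for v in self.drug_targets.values())

    @property
    def n_ds_edges(self) -> int:
        return sum(len(v) for v in self.drug_subs.values())


def build_tripartite(
    dti_net: DTINetwork,
    profiles: Mapping[str, Iterable[str]] | Sequence[SubstructureProfile],
    nces: Iterable[str] = (),
) -> TripartiteNetwork:
    """Join a DTI network with drug-substructure incidence profiles.

    Compounds in ``profiles`` must be drug nodes of the network or be
    declared new chemical entities (``nces``); NCEs enter with only D-S
    edges.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.compound_id: p.keys for p in profiles}
    nce_set = set(nces)
    known = set(dti_net.drugs)
    unknown = set(profiles) - known - nce_set
    if unknown:
        raise ValueError(
            f"profiles reference compounds that are neither drugs nor declared "
            f"NCEs: {sorted(unknown)[:5]}"
        )
    drug_targets = {d: dti_net.drug_targets(d) for d in known}
    for nce in nce_set - known:
        drug_targets[nce] = set()
    drug_subs = {d: set(profiles.get(d, ())) for d in drug_targets}
    return TripartiteNetwork(drug_targets, drug_subs)


def initial_resource_vector(
    drug: str,
    net: TripartiteNetwork,
    alpha: float = 0.1,
    alpha_to: str = "substructures",
) -> np.ndarray:
    """Unit resource placed on the query drug's neighbors.

    The class named by ``alpha_to`` shares mass ``alpha`` equally; the other
    class shares ``1 - alpha``. If one class is empty the other receives all
    the mass. The vector sums to 1.
    """
    if drug not in net.drug_targets:
        raise KeyError(f"unknown drug {drug!r}")
    targets = sorted(net.drug_targets[drug])
    subs = sorted(net.drug_subs[drug])
    if not targets and not subs:
        raise ValueError(f"drug {drug!r} is isolated; no neighbors to seed")
    sub_share = alpha if alpha_to == "substructures" else 1.0 - alpha
    target_share = 1.0 - sub_share
    if not targets:
        target_share, sub_share = 0.0, 1.0
    elif not subs:
        target_share, sub_share = 1.0, 0.0
    f0 = np.zeros(net.n_nodes)
    for t in targets:
        f0[net.index("target", t)] = target_share / len(targets)
    for s in subs:
        f0[net.index("sub", s)] = sub_share / len(subs)
    return f0


def transfer_matrix(
    net: TripartiteNetwork, beta: float = 0.1, gamma: float = -0.5
) -> sparse.csr_matrix:
    """Resource-transfer matrix W with W[i, j] = w(j -> i) * deg(i)**gamma.

    Outgoing shares: a drug sends mass ``1 - beta`` split equally over its
    target neighbors and ``beta`` over its substructure neighbors (the full
    mass to whichever class is non-empty if the other is empty); a target or
    substructure splits its mass equally over its drug neighbors. The
    recipient-degree damping deg(i)**gamma is applied without
    renormalization, so W is column-stochastic only at gamma = 0.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    rows, cols, vals = [], [], []

    def damp(kind: str, name: str) -> float:
        return float(net.degree(kind, name)) ** gamma

    for d in net.drugs:
        j = net.index("drug", d)
        targets = net.drug_targets[d]
        subs = net.drug_subs[d]
        sub_share = beta
        target_share = 1.0 - beta
        if not targets and not subs:
            continue
        if not targets:
            sub_share, target_share = 1.0, 0.0
        elif not subs:
            sub_share, target_share = 0.0, 1.0
        for t in targets:
            rows.append(net.index("target", t))
            cols.append(j)
            vals.append(target_share / len(targets) * damp("target", t))
        for s in subs:
            rows.append(net.index("sub", s))
            cols.append(j)
            vals.append(sub_share / len(subs) * damp("sub", s))
    for t in net.targets:
        j = net.index("target", t)
        drugs = net.target_drugs[t]
        for d in drugs:
            rows.append(net.index("drug", d))
            cols.append(j)
            vals.append(1.0 / len(drugs) * damp("drug", d))
    for s in net.subs:
        j = net.index("sub", s)
        drugs = net.sub_drugs[s]
        for d in drugs:
            rows.append(net.index("drug", d))
            cols.append(j)
            vals.append(1.0 / len(drugs) * damp("drug", d))
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(net.n_nodes, net.n_nodes)
    )


def diffuse(W: sparse.spmatrix, f0: np.ndarray, k: int) -> np.ndarray:
    """Apply the transfer matrix ``k`` times; ``k = 0`` returns ``f0``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    f0 = np.asarray(f0, dtype=float)
    if W.shape[1] != f0.shape[0]:
        raise ValueError(
            f"dimension mismatch: W is {W.shape}, f0 has length {f0.shape[0]}"
        )
    f = f0
    for _ in range(k):
        f = W @ f
    return f


def rank_candidate_targets(
    drug: str,
    final: np.ndarray,
    net: TripartiteNetwork,
    top_n: int = 20,
) -> list[tuple[str, float]]:
    """Targets not already linked to the drug, by descending final resource.

    Ties are broken by ascending target id; at most ``top_n`` are returned.
    """
    known = net.drug_targets[drug]
    candidates = [
        (t, float(final[net.index("target", t)]))
        for t in net.targets
        if t not in known
    ]
    candidates.sort(key=lambda ts: (-ts[1], ts[0]))
    return candidates[:top_n]


def predict_dti_network(
    dti_net: DTINetwork,
    profiles: Mapping[str, Iterable[str]] | Sequence[SubstructureProfile],
    params: InferenceParams = InferenceParams(),
    nces: Iterable[str] = (),
) -> pd.DataFrame:
    """Batch target prediction for every drug; deterministic.

    Returns a frame (drug, target, score, rank) concatenating each drug's
    ranked top-``top_n`` candidates.
    """
    net = build_tripartite(dti_net, profiles, nces)
    W = transfer_matrix(net, params.beta, params.gamma)
    rows = []
    for drug in net.drugs:
        if not net.drug_targets[drug] and not net.drug_subs[drug]:
            continue
        f0 = initial_resource_vector(drug, net, params.alpha, params.alpha_to)
        final = diffuse(W, f0, params.k)
        for rank, (target, score) in enumerate(
            rank_candidate_targets(drug, final, net, params.top_n), start=1
        ):
            rows.append((drug, target, score, rank))
    return pd.DataFrame(rows, columns=["drug", "target", "score", "rank"])


class SubstructureDiffusion:
    """Convenience wrapper binding a DTI network, profiles and parameters."""

    def __init__(
        self,
        dti_net: DTINetwork,
        profiles: Mapping[str, Iterable[str]] | Sequence[SubstructureProfile],
        params: InferenceParams = InferenceParams(),
        nces: Iterable[str] = (),
    ) -> None:
        self.dti_net = dti_net
        self.profiles = profiles
        self.params = params
        self.nces = tuple(nces)

    def predict(self) -> pd.DataFrame:
        return predict_dti_network(
            self.dti_net, self.profiles, self.params, self.nces
        )
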