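"""Drug-target interaction (DTI) networks of natural products.

Raw bioactivity records are filtered with five criteria — (i) a binding
potency (Ki, Kd, IC50 or EC50) of at most 10 uM, (ii) a human target,
(iii) a UniProt accession, (iv) a standardizable structure and (v) at
least one carbon atom — then deduplicated by InChIKey and assembled into
a bipartite drug-target graph whose edges carry provenance (experimental
or predicted) and whose targets may be flagged as aging-associated
proteins (AAPs).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ALLOWED_ACTIVITY_TYPES = frozenset({"KI", "KD", "IC50", "EC50"})
DEFAULT_ACTIVITY_THRESHOLD_UM = 10.0
DEFAULT_ORGANISM = "Homo sapiens"


class StandardizationError(ValueError):
    """Structure cannot be parsed or standardized."""


class NoCarbonError(StandardizationError):
    """Structure has no carbon-containing fragment."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement linking a compound to a target."""

    compound_id: str
    smiles: str
    inchikey: str | None
    uniprot: str
    organism: str
    activity_type: str
    activity_value_um: float


@dataclass
class CompoundRecord:
    """A standardized, InChIKey-deduplicated compound."""

    compound_id: str
    smiles: str
    inchikey: str
    name: str | None = None
    approved: bool | None = None
    aliases: list[str] = field(default_factory=list)


def standardize_structure(smiles: str) -> tuple[str, str]:
    """Canonicalize a structure after stripping salt/counter-ion fragments.

    Keeps the largest carbon-containing fragment (ties broken by heavy-atom
    count, then by canonical-SMILES order) and returns its canonical SMILES
    and InChIKey.

    Raises :class:`StandardizationError` for unparsable input and
    :class:`NoCarbonError` when no fragment contains carbon.
    """
    mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    carbon_frags = []
    for frag in frags:
        if any(atom.GetAtomicNum() == 6 for atom in frag.GetAtoms()):
            carbon_frags.append(frag)
    if not carbon_frags:
        raise NoCarbonError(f"no carbon-containing fragment in {smiles!r}")
    # largest fragment by heavy atoms; canonical SMILES breaks exact ties
    best = max(
        carbon_frags,
        key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
    )
    canonical = Chem.MolToSmiles(best)
    inchikey = Chem.MolToInchiKey(best)
    if not inchikey:
        raise StandardizationError(f"no InChIKey derivable for {smiles!r}")
    return canonical, inchikey


def _normalize_organism(organism: str) -> str:
    return " ".join(str(organism).split()).casefold()


def filter_activity_records(
    records: Sequence[ActivityRecord],
    threshold_um: float = DEFAULT_ACTIVITY_THRESHOLD_UM,
    organism: str = DEFAULT_ORGANISM,
) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Apply the five DTI quality criteria; return kept records + rejection log.

    The rejection log records, per dropped record, the first criterion it
    failed (``i``..``v``). Kept records have their SMILES and InChIKey
    replaced by the standardized forms. Filtering is order-independent.
    """
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    want_organism = _normalize_organism(organism)

    kept: list[ActivityRecord] = []
    rejections: list[tuple[int, str, str]] = []
    for idx, rec in enumerate(records):
        atype = str(rec.activity_type).strip().upper()
        value = rec.activity_value_um
        if (
            atype not in ALLOWED_ACTIVITY_TYPES
            or not math.isfinite(value)
            or value <= 0
            or value > threshold_um
        ):
            rejections.append((idx, "i", rec.compound_id))
            continue
        if _normalize_organism(rec.organism) != want_organism:
            rejections.append((idx, "ii", rec.compound_id))
            continue
        if not str(rec.uniprot).strip():
            rejections.append((idx, "iii", rec.compound_id))
            continue
        try:
            canonical, inchikey = standardize_structure(rec.smiles)
        except NoCarbonError:
            rejections.append((idx, "v", rec.compound_id))
            continue
        except StandardizationError:
            rejections.append((idx, "iv", rec.compound_id))
            continue
        kept.append(
            ActivityRecord(
                compound_id=rec.compound_id,
                smiles=canonical,
                inchikey=inchikey,
                uniprot=str(rec.uniprot).strip(),
                organism=rec.organism,
                activity_type=atype,
                activity_value_um=float(value),
            )
        )
    log = pd.DataFrame(
        rejections, columns=["record_index", "failed_criterion", "compound_id"]
    )
    return kept, log


def dedup_compounds(records: Sequence[ActivityRecord]) -> list[CompoundRecord]:
    """Collapse standardized records to one compound per InChIKey.

    The first-seen compound id is kept; other ids sharing the key are
    recorded as aliases.
    """
    by_key: dict[str, CompoundRecord] = {}
    for rec in records:
        if not rec.inchikey:
            raise ValueError(
                f"record for {rec.compound_id!r} lacks an InChIKey; standardize first"
            )
        comp = by_key.get(rec.inchikey)
        if comp is None:
            by_key[rec.inchikey] = CompoundRecord(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                inchikey=rec.inchikey,
            )
        elif rec.compound_id != comp.compound_id and rec.compound_id not in comp.aliases:
            comp.aliases.append(rec.compound_id)
    return list(by_key.values())


class DTINetwork:
    """Bipartite drug-target graph with edge provenance and AAP target flags."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------

    def add_drug(self, drug_id: str) -> None:
        self.graph.add_node(("drug", drug_id), kind="drug")

    def add_target(self, accession: str, gene_symbol: str | None = None) -> None:
        node = ("target", accession)
        if node in self.graph and gene_symbol is None:
            return
        self.graph.add_node(
            node,
            kind="target",
            gene_symbol=gene_symbol,
            aap=self.graph.nodes.get(node, {}).get("aap", False),
        )

    def add_edge(
        self,
        drug_id: str,
        accession: str,
        provenance: str,
        activity_um: float | None = None,
    ) -> None:
        if provenance not in ("experimental", "predicted"):
            raise ValueError(f"unknown provenance {provenance!r}")
        d, t = ("drug", drug_id), ("target", accession)
        if d not in self.graph:
            raise ValueError(f"dangling edge: unknown drug {drug_id!r}")
        if t not in self.graph:
            raise ValueError(f"dangling edge: unknown target {accession!r}")
        if self.graph.has_edge(d, t):
            data = self.graph.edges[d, t]
            data["provenance"] = set(data["provenance"]) | {provenance}
            old = data.get("activity_um")
            if activity_um is not None and (old is None or activity_um < old):
                data["activity_um"] = activity_um
        else:
            self.graph.add_edge(
                d, t, provenance={provenance}, activity_um=activity_um
            )

    # -- views ---------------------------------------------------------

    @property
    def drugs(self) -> list[str]:
        return sorted(n[1] for n, d in self.graph.nodes(data=True) if d["kind"] == "drug")

    @property
    def targets(self) -> list[str]:
        return sorted(
            n[1] for n, d in self.graph.nodes(data=True) if d["kind"] == "target"
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def drug_targets(self, drug_id: str) -> set[str]:
        node = ("drug", drug_id)
        if node not in self.graph:
            raise KeyError(f"unknown drug {drug_id!r}")
        return {t for _, t in self.graph.neighbors(node)}

    def target_gene(self, accession: str) -> str | None:
        return self.graph.nodes[("target", accession)].get("gene_symbol")

    def is_aap_target(self, accession: str) -> bool:
        return bool(self.graph.nodes[("target", accession)].get("aap", False))

    def edges(self) -> Iterable[tuple[str, str, dict]]:
        for (k1, a), (k2, b), data in self.graph.edges(data=True):
            if k1 == "drug":
                yield a, b, data
            else:
                yield b, a, data

    def copy(self) -> "DTINetwork":
        out = DTINetwork()
        out.graph = self.graph.copy()
        return out


def build_network(
    dtis: Iterable[tuple[str, str] | tuple[str, str, float]],
    provenance: str,
    target_genes: Mapping[str, str] | None = None,
) -> DTINetwork:
    """Build a bipartite network from (drug, target[, activity]) pairs."""
    net = DTINetwork()
    target_genes = target_genes or {}
    for edge in dtis:
        drug, target = edge[0], edge[1]
        activity = float(edge[2]) if len(edge) > 2 and edge[2] is not None else None
        net.add_drug(drug)
        net.add_target(target, target_genes.get(target))
        net.add_edge(drug, target, provenance, activity)
    return net


def merge_networks(net_a: DTINetwork, net_b: DTINetwork) -> DTINetwork:
    """Union of two networks; shared edges carry both provenances."""
    merged = net_a.copy()
    for n, data in net_b.graph.nodes(data=True):
        if data["kind"] == "drug":
            merged.add_drug(n[1])
        else:
            merged.add_target(n[1], data.get("gene_symbol"))
            if data.get("aap"):
                merged.graph.nodes[n]["aap"] = True
    for drug, target, data in net_b.edges():
        for prov in sorted(data["provenance"]):
            merged.add_edge(drug, target, prov, data.get("activity_um"))
    return merged


@dataclass(frozen=True)
class NetworkStats:
    n_drugs: int
    n_targets: int
    n_aap_targets: int
    n_edges: int
    sparsity_pct: float
    mean_drug_degree: float
    drug_degrees: dict[str, int]
    target_degrees: dict[str, int]

    @property
    def sparsity_pct_2dp(self) -> float:
        """Sparsity truncated to 2 decimals (the reporting convention of the
        reference network tables: 2,408/(224*494) = 2.176% prints as 2.17)."""
        return math.floor(self.sparsity_pct * 100.0) / 100.0


def network_stats(net: DTINetwork) -> NetworkStats:
    """Global statistics: counts, sparsity (%), per-node degrees.

    Sparsity is 100 * edges / (drugs * targets), the filled fraction of the
    bipartite adjacency matrix.
    """
    drugs, targets = net.drugs, net.targets
    if not drugs or not targets:
        raise ValueError("network must contain at least one drug and one target")
    n_edges = net.n_edges
    drug_deg = {d: net.graph.degree(("drug", d)) for d in drugs}
    target_deg = {t: net.graph.degree(("target", t)) for t in targets}
    return NetworkStats(
        n_drugs=len(drugs),
        n_targets=len(targets),
        n_aap_targets=sum(net.is_aap_target(t) for t in targets),
        n_edges=n_edges,
        sparsity_pct=100.0 * n_edges / (len(drugs) * len(targets)),
        mean_drug_degree=n_edges / len(drugs),
        drug_degrees=drug_deg,
        target_degrees=target_deg,
    )


def annotate_aap_targets(
    net: DTINetwork,
    aag_symbols: Iterable[str],
    target_gene_map: Mapping[str, str] | None = None,
) -> tuple[DTINetwork, int]:
    """Flag targets whose encoding gene is in the AAG set; return (net, N_AT).

    ``target_gene_map`` supplies accession -> gene symbol for targets
    lacking one; unmapped targets are flagged False with a warning.
    """
    aag = {str(s).strip().upper() for s in aag_symbols}
    target_gene_map = target_gene_map or {}
    out = net.copy()
    n_at = 0
    unmapped = []
    for t in out.targets:
        node = ("target", t)
        gene = target_gene_map.get(t) or out.target_gene(t)
        if gene is not None:
            out.graph.nodes[node]["gene_symbol"] = gene
        if gene is None:
            unmapped.append(t)
            out.graph.nodes[node]["aap"] = False
            continue
        flag = str(gene).strip().upper() in aag
        out.graph.nodes[node]["aap"] = flag
        n_at += flag
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} targets without a gene symbol left unflagged"
        )
    return out, n_at


def extract_drug_subnetwork(net: DTINetwork, drug_ids: Iterable[str]) -> DTINetwork:
    """Induced subgraph on the given drugs and their target neighbors."""
    drug_ids = list(drug_ids)
    for d in drug_ids:
        if ("drug", d) not in net.graph:
            raise KeyError(f"unknown drug {d!r}")
    nodes = {("drug", d) for d in drug_ids}
    for d in drug_ids:
        nodes |= set(net.graph.neighbors(("drug", d)))
    sub = DTINetwork()
    sub.graph = net.graph.subgraph(nodes).copy()
    return sub


def compare_degree_distributions(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "greater",
) -> float:
    """One-sided rank-sum (Mann-Whitney) p-value comparing two degree samples.

    ``alternative='greater'`` tests whether ``sample_a`` is stochastically
    greater than ``sample_b``. Small samples (<= 8 per side) are handled by
    exact enumeration of group-label assignments with midranks: the p-value
    is inclusive (P(S >= s)) when the pooled sample has no ties and mid-p
    (#{S > s} + 0.5 * #{S = s}) / M when it does. Larger samples use the
    tie-corrected normal approximation; a degenerate null (zero variance)
    yields p = 0.5.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if alternative == "less":
        return compare_degree_distributions(b, a, "greater")

    if max(a.size, b.size) <= 8:
        combined = np.concatenate([a, b])
        ranks = sps.rankdata(combined)  # midranks
        observed = ranks[: a.size].sum()
        has_ties = np.unique(combined).size < combined.size
        total = greater = equal = 0
        for idx in itertools.combinations(range(combined.size), a.size):
            s = ranks[list(idx)].sum()
            total += 1
            if s > observed + 1e-9:
                greater += 1
            elif abs(s - observed) <= 1e-9:
                equal += 1
        if has_ties:
            return (greater + 0.5 * equal) / total
        return (greater + equal) / total

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
            p = float(res.pvalue)
        except ValueError:
            p = float("nan")
    if not math.isfinite(p):  # degenerate null (all values tied)
        return 0.5
    return p


def tanimoto_distance(profile_a: frozenset, profile_b: frozenset) -> float:
    """1 - |A∩B|/|A∪B| over substructure key sets; two empty sets are at 0."""
    union = len(profile_a | profile_b)
    if union == 0:
        return 0.0
    return 1.0 - len(profile_a & profile_b) / union


def cluster_compounds(
    profiles: Mapping[str, Iterable],
    k: int = 10,
    seed: int = 0,
) -> tuple[dict[str, int], list[str]]:
    """Partition compounds into ``k`` groups under Tanimoto distance (PAM).

    Returns (labels by compound id, medoid id per cluster). The medoid is
    the member minimizing summed distance within its cluster. Deterministic:
    greedy BUILD initialization followed by SWAP refinement; ties broken by
    compound-id order.
    """
    ids = sorted(profiles)
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of compounds ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    sets = [frozenset(profiles[i]) for i in ids]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = tanimoto_distance(sets[i], sets[j])

    # BUILD: greedily add the medoid giving the largest cost reduction
    medoids: list[int] = []
    for _ in range(k):
        best_i, best_cost = -1, np.inf
        for i in range(n):
            if i in medoids:
                continue
            trial = medoids + [i]
            cost = dist[:, trial].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best_i, best_cost = i, cost
        medoids.append(best_i)

    # SWAP: replace a medoid with a non-medoid while cost decreases
    def total_cost(meds: list[int]) -> float:
        return dist[:, meds].min(axis=1).sum()

    improved = True
    while improved:
        improved = False
        current = total_cost(medoids)
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                if total_cost(trial) < current - 1e-12:
                    medoids = trial
                    current = total_cost(medoids)
                    improved = True

    medoids = sorted(medoids)
    assign = np.argmin(dist[:, medoids], axis=1)
    # recompute the medoid of each realized cluster (lowest index on ties)
    final_medoids: list[int] = []
    for c in range(k):
        members = np.flatnonzero(assign == c)
        if members.size == 0:
            final_medoids.append(medoids[c])
            continue
        within = dist[np.ix_(members, members)].sum(axis=1)
        final_medoids.append(int(members[int(np.argmin(within))]))
    labels = {ids[i]: int(assign[i]) for i in range(n)}
    return labels, [ids[m] for m in final_medoids]
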