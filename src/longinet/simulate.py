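"""Synthetic data generation with known ground truth.

Every input the pipeline consumes can be generated here: a protein-coding
gene universe with an aging-associated (AAP) subset, per-organism aging
gene lists with an ortholog table whose pooled counts are known by
construction, compounds with substructure profiles and simple valid
SMILES, activity records with per-record pass/fail labels for the five
filter criteria, and drug-target networks with heavy-tailed drug degrees
and a planted subset of drugs whose targets are AAP-enriched at a
configurable fraction pi.

Defaults emulate the study conditions: a 20,462-gene universe with a
411-gene AAP subset; organism lists sized so that 130 cross-organism
genes (28 shared with a 309-gene human list) pool to 411; and a planted
cohort of 200 drugs with degrees 3-30 (truncated power law, exponent
2.2), 20 of them planted at pi = 0.5 against an AAP-target background
rate matching the genomic rate (~2%).

All generators are bit-reproducible under a fixed seed, and emitted
truth labels are validated against the emitted data at generation time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import NON_HUMAN, OrganismGeneList, OrthologTable
from .network import ActivityRecord, DTINetwork, annotate_aap_targets, build_network

# simple, valid structures reused cyclically for standardization-path tests
_SMILES_TEMPLATES = (
    "CCO",
    "c1ccccc1O",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CCN(CC)CC",
    "c1ccc2[nH]ccc2c1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "COc1cc(C=CC(=O)O)ccc1O",
    "Oc1ccc(cc1)C2=CC(=O)c3c(O)cc(O)cc3O2",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # gene universe
    n_genes: int = 20_462
    n_aap: int = 411
    # ortholog curation shapes
    n_human_aag: int = 309
    n_orth_support1: int = 876  # genes seen in exactly one non-human organism
    n_orth_support2: int = 118  # exactly two organisms
    n_orth_support3: int = 12  # exactly three organisms
    overlap_human_orth: int = 28  # human list ∩ (support >= 2) set
    # drug-target network
    n_drugs: int = 200
    n_targets: int = 400
    n_aap_targets: int = 8  # ~2% of targets, matching the genomic AAP rate
    degree_exponent: float = 2.2
    min_degree: int = 3
    max_degree: int = 30
    n_planted: int = 20
    pi: float = 0.5  # planted per-edge AAP-target probability
    # substructure profiles
    n_sub_keys: int = 40
    n_motif_keys: int = 8  # shared block that makes planted drugs similar
    keys_per_drug: int = 6
    # activity-record mix
    n_pass_records: int = 30
    n_fail_per_criterion: int = 2

    def __post_init__(self) -> None:
        if self.n_aap > self.n_genes:
            raise ValueError("n_aap cannot exceed n_genes")
        if self.n_planted > self.n_drugs:
            raise ValueError("n_planted cannot exceed n_drugs")
        if self.n_aap_targets > self.n_targets:
            raise ValueError("n_aap_targets cannot exceed n_targets")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.min_degree < 1 or self.max_degree < self.min_degree:
            raise ValueError("need 1 <= min_degree <= max_degree")
        if self.overlap_human_orth > min(
            self.n_human_aag, self.n_orth_support2 + self.n_orth_support3
        ):
            raise ValueError("configured human/ortholog overlap is infeasible")
        # organism-list sizes vs. universe size are validated at generation
        # time (gen_ortholog_catalog), so small-universe network studies need
        # not reconfigure the curation shapes they never generate


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside generated data."""

    planted_drugs: list[str] = field(default_factory=list)
    pi: float = 0.0
    filter_pass_labels: list[bool] = field(default_factory=list)
    expected: dict = field(default_factory=dict)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def gen_universe(config: GeneratorConfig) -> tuple[list[str], set[str]]:
    """N synthetic gene symbols plus a K-gene AAP subset, seeded."""
    genes = [f"G{i:06d}" for i in range(1, config.n_genes + 1)]
    rng = _rng(config, 1)
    aap = set(
        np.array(genes)[
            rng.choice(config.n_genes, size=config.n_aap, replace=False)
        ].tolist()
    )
    return genes, aap


@dataclass
class OrthologCatalogData:
    human_list: OrganismGeneList
    organism_lists: list[OrganismGeneList]
    table: OrthologTable
    truth: SyntheticTruth


def gen_ortholog_catalog(config: GeneratorConfig) -> OrthologCatalogData:
    """Per-organism lists + ortholog table with configured pooled counts.

    Non-human evidence is planted by assigning each cross-organism gene to
    exactly 1, 2 or 3 of {CE, DM, MM, SC} (cycling deterministically over
    the organism combinations), with source gene ids distinct from human
    symbols so every non-human hit must pass through the ortholog table.

    The genes that survive curation (support >= 2, plus the human list) are
    drawn from the universe's AAP subset, so with the default sizes
    (118 + 12 cross-organism, 309 human, 28 shared) the pooled catalogue is
    exactly the 411-gene AAP set the network generator plants against.
    """
    rng = _rng(config, 2)
    genes, aap = gen_universe(config)
    aap_perm = [sorted(aap)[i] for i in rng.permutation(len(aap))]
    non_aap = sorted(set(genes) - aap)

    n_ge2 = config.n_orth_support2 + config.n_orth_support3
    ge2 = aap_perm[:n_ge2]
    support2 = ge2[: config.n_orth_support2]
    support3 = ge2[config.n_orth_support2 :]
    # human list: the configured overlap with the support>=2 pool, the rest
    # from remaining AAP genes (topped up from outside if the AAP subset is
    # too small for the configured sizes)
    n_human_only = config.n_human_aag - config.overlap_human_orth
    remaining_aap = aap_perm[n_ge2:]
    human_only = remaining_aap[:n_human_only]
    short = n_human_only - len(human_only)
    extra_pool = [non_aap[i] for i in rng.permutation(len(non_aap))]
    if short > 0:
        human_only = human_only + extra_pool[:short]
        extra_pool = extra_pool[short:]
    human_genes = set(ge2[: config.overlap_human_orth]) | set(human_only)
    # single-organism genes never reach the pooled set; draw them outside it
    support1 = extra_pool[: config.n_orth_support1]
    if len(support1) < config.n_orth_support1:
        raise ValueError("universe too small for configured organism lists")

    singles = itertools.cycle(NON_HUMAN)
    pairs = itertools.cycle(list(itertools.combinations(NON_HUMAN, 2)))
    triples = itertools.cycle(list(itertools.combinations(NON_HUMAN, 3)))

    per_org: dict[str, set[str]] = {org: set() for org in NON_HUMAN}
    rows: list[tuple[str, str, str]] = []
    counters = {org: 0 for org in NON_HUMAN}

    def plant(sym: str, orgs: Sequence[str]) -> None:
        for org in orgs:
            counters[org] += 1
            src = f"{org.lower()}_src{counters[org]:05d}"
            per_org[org].add(src)
            rows.append((org, src, sym))

    for sym in support1:
        plant(sym, (next(singles),))
    for sym in support2:
        plant(sym, next(pairs))
    for sym in support3:
        plant(sym, next(triples))

    organism_lists = [
        OrganismGeneList(org, per_org[org]) for org in NON_HUMAN
    ]
    human_list = OrganismGeneList("HS", human_genes)
    table = OrthologTable(rows)

    truth = SyntheticTruth(
        expected={
            "union_at_least_one": config.n_orth_support1
            + config.n_orth_support2
            + config.n_orth_support3,
            "support_ge2": config.n_orth_support2 + config.n_orth_support3,
            "support_ge3": config.n_orth_support3,
            "human_count": config.n_human_aag,
            "overlap": config.overlap_human_orth,
            "pooled": config.n_orth_support2
            + config.n_orth_support3
            + config.n_human_aag
            - config.overlap_human_orth,
            "pooled_equals_aap": set(ge2) | human_genes == aap,
        }
    )
    return OrthologCatalogData(human_list, organism_lists, table, truth)


def gen_compounds(
    config: GeneratorConfig,
) -> tuple[list[dict], dict[str, set[str]], dict[str, str]]:
    """Compound records, substructure profiles and the key dictionary.

    Planted drugs draw half of their keys from a shared motif block so that
    substructure-mediated diffusion links them; the synthetic dictionary is
    a plain key list (key -> key), usable wherever pattern matching is not
    under test.
    """
    rng = _rng(config, 3)
    keys = [f"S{i:03d}" for i in range(config.n_sub_keys)]
    motif = keys[: config.n_motif_keys]
    rest = keys[config.n_motif_keys :]
    drug_ids = [f"D{i:04d}" for i in range(1, config.n_drugs + 1)]
    planted = set(drug_ids[: config.n_planted])

    compounds = []
    profiles: dict[str, set[str]] = {}
    for i, drug in enumerate(drug_ids):
        smiles = _SMILES_TEMPLATES[i % len(_SMILES_TEMPLATES)]
        compounds.append({"compound_id": drug, "smiles": smiles})
        kp = config.keys_per_drug
        if drug in planted and motif:
            n_m = max(1, kp // 2)
            chosen = set(
                np.array(motif)[
                    rng.choice(len(motif), size=min(n_m, len(motif)), replace=False)
                ].tolist()
            )
            pool = rest if rest else keys
            chosen |= set(
                np.array(pool)[
                    rng.choice(len(pool), size=min(kp - len(chosen), len(pool)), replace=False)
                ].tolist()
            )
        else:
            pool = rest if rest else keys
            chosen = set(
                np.array(pool)[
                    rng.choice(len(pool), size=min(kp, len(pool)), replace=False)
                ].tolist()
            )
        profiles[drug] = chosen
    dictionary = {k: k for k in keys}
    return compounds, profiles, dictionary


def gen_activity_records(
    config: GeneratorConfig,
) -> tuple[list[ActivityRecord], list[bool]]:
    """Activity records mixing passing rows with one violation per criterion.

    The first passing record sits exactly at the 10 uM threshold (the
    inclusive boundary); labels mark which records the five-criteria filter
    must keep.
    """
    rng = _rng(config, 4)
    records: list[ActivityRecord] = []
    labels: list[bool] = []
    types = ("IC50", "Ki", "Kd", "EC50")
    for i in range(config.n_pass_records):
        value = 10.0 if i == 0 else float(rng.uniform(0.01, 10.0))
        records.append(
            ActivityRecord(
                compound_id=f"D{(i % config.n_drugs) + 1:04d}",
                smiles=_SMILES_TEMPLATES[i % len(_SMILES_TEMPLATES)],
                inchikey=None,
                uniprot=f"P{10000 + i}",
                organism="Homo sapiens",
                activity_type=types[i % len(types)],
                activity_value_um=value,
            )
        )
        labels.append(True)
    fails = [
        # (i) wrong type or over-threshold potency
        dict(activity_type="AC50", activity_value_um=1.0),
        dict(activity_value_um=15.0),
        # (ii) non-human target
        dict(organism="Rattus norvegicus"),
        dict(organism="Mus musculus"),
        # (iii) missing accession
        dict(uniprot=""),
        dict(uniprot="   "),
        # (iv) unstandardizable structure
        dict(smiles="not_a_smiles(("),
        dict(smiles="C1CC"),
        # (v) no carbon atom
        dict(smiles="[Na+].[Cl-]"),
        dict(smiles="O=S(=O)(O)O"),
    ]
    base = dict(
        compound_id="DFAIL",
        smiles="CCO",
        inchikey=None,
        uniprot="P99999",
        organism="Homo sapiens",
        activity_type="IC50",
        activity_value_um=1.0,
    )
    per = config.n_fail_per_criterion
    chosen_fails = [fails[2 * c + j] for c in range(5) for j in range(min(per, 2))]
    for override in chosen_fails:
        records.append(ActivityRecord(**{**base, **override}))
        labels.append(False)
    return records, labels


def _sample_degrees(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.min_degree, min(config.max_degree, config.n_targets)
    support = np.arange(lo, hi + 1)
    pmf = support.astype(float) ** (-config.degree_exponent)
    pmf /= pmf.sum()
    return rng.choice(support, size=config.n_drugs, p=pmf)


@dataclass
class SyntheticDTIData:
    net: DTINetwork  # AAP-annotated experimental network
    target_gene_map: dict[str, str]
    aap_genes: set[str]
    universe: list[str]
    truth: SyntheticTruth


def gen_dti_network(config: GeneratorConfig) -> SyntheticDTIData:
    """Experimental DTI network with heavy-tailed degrees and planted signal.

    Planted drugs pick each target from the AAP-encoded pool with
    probability pi and from the rest otherwise; null drugs pick uniformly,
    so their AAP-target rate is the background n_aap_targets / n_targets.
    Emitted truth is validated against the network before returning.
    """
    rng = _rng(config, 5)
    universe, aap_genes = gen_universe(config)
    non_aap = sorted(set(universe) - aap_genes)
    aap_sorted = sorted(aap_genes)
    target_ids = [f"T{i:04d}" for i in range(1, config.n_targets + 1)]
    aap_gene_pick = rng.choice(len(aap_sorted), size=config.n_aap_targets, replace=False)
    non_aap_pick = rng.choice(
        len(non_aap), size=config.n_targets - config.n_aap_targets, replace=False
    )
    target_gene_map: dict[str, str] = {}
    for i, t in enumerate(target_ids):
        if i < config.n_aap_targets:
            target_gene_map[t] = aap_sorted[aap_gene_pick[i]]
        else:
            target_gene_map[t] = non_aap[non_aap_pick[i - config.n_aap_targets]]

    aap_targets = target_ids[: config.n_aap_targets]
    other_targets = target_ids[config.n_aap_targets :]
    drug_ids = [f"D{i:04d}" for i in range(1, config.n_drugs + 1)]
    planted = drug_ids[: config.n_planted]
    degrees = _sample_degrees(config, rng)

    edges: list[tuple[str, str]] = []
    for drug, degree in zip(drug_ids, degrees):
        if drug in planted:
            chosen: set[str] = set()
            aap_pool = list(aap_targets)
            other_pool = list(other_targets)
            for _ in range(int(degree)):
                use_aap = rng.random() < config.pi
                pool = aap_pool if (use_aap and aap_pool) else other_pool
                if not pool:
                    pool = aap_pool or other_pool
                pick = pool.pop(int(rng.integers(len(pool))))
                chosen.add(pick)
            targets = chosen
        else:
            idx = rng.choice(config.n_targets, size=int(degree), replace=False)
            targets = {target_ids[i] for i in idx}
        edges.extend((drug, t) for t in sorted(targets))

    net = build_network(edges, "experimental", target_gene_map)
    net, n_at = annotate_aap_targets(net, aap_genes, target_gene_map)

    truth = SyntheticTruth(
        planted_drugs=list(planted),
        pi=config.pi,
        expected={
            "n_drugs": config.n_drugs,
            "n_targets": config.n_targets,
            "n_aap_targets": config.n_aap_targets,
            "n_edges": len(edges),
        },
    )
    # self-check: truth must validate against the emitted network
    stats_ok = (
        len(net.drugs) == config.n_drugs
        and len(net.targets) <= config.n_targets
        and n_at <= config.n_aap_targets
        and net.n_edges == len(edges)
    )
    if not stats_ok:
        raise RuntimeError("generator self-check failed: truth/data mismatch")
    # planted labels must validate: x computed from the emitted network
    for drug in planted:
        genes = {target_gene_map[t] for t in net.drug_targets(drug)}
        if len(genes & aap_genes) != sum(
            1 for t in net.drug_targets(drug) if net.is_aap_target(t)
        ):
            raise RuntimeError("generator self-check failed: AAP flags mismatch")
    return SyntheticDTIData(net, target_gene_map, aap_genes, universe, truth)


def activity_records_for_network(
    net: DTINetwork, config: GeneratorConfig
) -> tuple[list[ActivityRecord], list[bool]]:
    """Passing activity records reproducing a network's edges, plus the
    labelled failing mix, so the five-criteria filter rebuilds the network."""
    records: list[ActivityRecord] = []
    labels: list[bool] = []
    for i, (drug, target, _) in enumerate(sorted(net.edges())):
        records.append(
            ActivityRecord(
                compound_id=drug,
                smiles=_SMILES_TEMPLATES[i % len(_SMILES_TEMPLATES)],
                inchikey=None,
                uniprot=target,
                organism="Homo sapiens",
                activity_type=("IC50", "Ki", "Kd", "EC50")[i % 4],
                activity_value_um=float(1 + i % 9),
            )
        )
        labels.append(True)
    fail_records, fail_labels = gen_activity_records(
        GeneratorConfig(seed=config.seed, n_pass_records=1)
    )
    records.extend(fail_records[1:])  # drop the single passing row
    labels.extend(fail_labels[1:])
    return records, labels


def generate_fixture(config: GeneratorConfig, outdir: str) -> SyntheticTruth:
    """Materialize a full input directory + truth JSON for the pipeline.

    Writes gene_lists.tsv, orthologs.tsv, activity.tsv, profiles.tsv,
    target_genes.tsv, config.yaml and truth.json in the dialects the
    pipeline reads.
    """
    import json
    from pathlib import Path

    from . import io as lio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    ortho = gen_ortholog_catalog(config)
    lio.write_gene_lists([ortho.human_list, *ortho.organism_lists], out / "gene_lists.tsv")
    lio.write_ortholog_table(ortho.table, out / "orthologs.tsv")

    dti = gen_dti_network(config)
    records, labels = activity_records_for_network(dti.net, config)
    lio.write_activity_records(records, out / "activity.tsv")

    _, profiles, _ = gen_compounds(config)
    lio.write_profiles(profiles, out / "profiles.tsv")

    with open(out / "target_genes.tsv", "w") as fh:
        fh.write("# accession\tgene_symbol\n")
        for acc, gene in sorted(dti.target_gene_map.items()):
            fh.write(f"{acc}\t{gene}\n")

    truth = SyntheticTruth(
        planted_drugs=dti.truth.planted_drugs,
        pi=config.pi,
        filter_pass_labels=labels,
        expected={**ortho.truth.expected, **dti.truth.expected},
    )
    (out / "truth.json").write_text(
        json.dumps(
            {
                "planted_drugs": truth.planted_drugs,
                "pi": truth.pi,
                "filter_pass_labels": truth.filter_pass_labels,
                "expected": truth.expected,
            },
            indent=2,
        )
    )
    pipeline_cfg = {
        "gene_lists": str(out / "gene_lists.tsv"),
        "ortholog_table": str(out / "orthologs.tsv"),
        "activity_records": str(out / "activity.tsv"),
        "profiles": str(out / "profiles.tsv"),
        "target_gene_map": str(out / "target_genes.tsv"),
        "output_dir": str(out / "results"),
        "seed": config.seed,
    }
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(pipeline_cfg))
    return truth
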