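"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV/CSV with headers; gene lists allow ``#`` comments;
gene-set collections use the standard GMT dialect. Activity values are
converted to micromolar on load from an optional ``activity_units``
column (uM default; pM/nM/mM/M accepted).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .catalog import AAGCatalog, OrganismGeneList, OrthologTable
from .network import ActivityRecord, DTINetwork, build_network

_UNIT_TO_UM = {
    "pm": 1e-6,
    "nm": 1e-3,
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,
    "mm": 1e3,
    "m": 1e6,
}


def read_gene_lists(path: str | Path) -> list[OrganismGeneList]:
    """Read a 2-column (organism, symbol) TSV; '#' comments allowed."""
    per_org: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed gene-list line: {line!r}")
        per_org.setdefault(parts[0].strip().upper(), set()).add(parts[1].strip())
    return [OrganismGeneList(org, genes) for org, genes in sorted(per_org.items())]


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a 3-column (organism, source_gene, human_symbol) TSV."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed ortholog line: {line!r}")
        if parts[0].strip().lower() == "organism":  # header row
            continue
        rows.append((parts[0], parts[1], parts[2]))
    return OrthologTable(rows)


def write_gene_lists(lists: Iterable[OrganismGeneList], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# organism\tsymbol\n")
        for gl in lists:
            for gene in sorted(gl.genes):
                fh.write(f"{gl.organism}\t{gene}\n")


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: term, description, members..."""
    collections: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need term, desc, members): {line!r}")
        collections[parts[0]] = {g for g in parts[2:] if g}
    return collections


def write_catalog(catalog: AAGCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_activity_records(path: str | Path) -> list[ActivityRecord]:
    """Read activity records from CSV/TSV (sniffed by extension).

    Expected columns: compound_id, smiles, inchikey (optional), uniprot,
    organism, activity_type, activity_value, activity_units (optional,
    default uM).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"compound_id", "smiles", "uniprot", "organism", "activity_type", "activity_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        units = getattr(row, "activity_units", "uM") or "uM"
        factor = _UNIT_TO_UM.get(str(units).strip().lower())
        if factor is None:
            raise ValueError(f"unknown activity units {units!r}")
        try:
            value = float(row.activity_value) * factor
        except ValueError:
            value = float("nan")
        records.append(
            ActivityRecord(
                compound_id=row.compound_id,
                smiles=row.smiles,
                inchikey=getattr(row, "inchikey", "") or None,
                uniprot=row.uniprot,
                organism=row.organism,
                activity_type=row.activity_type,
                activity_value_um=value,
            )
        )
    return records


def write_activity_records(records: Iterable[ActivityRecord], path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "inchikey": r.inchikey or "",
            "uniprot": r.uniprot,
            "organism": r.organism,
            "activity_type": r.activity_type,
            "activity_value": r.activity_value_um,
            "activity_units": "uM",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_profiles(path: str | Path) -> dict[str, set[str]]:
    """Read (compound_id, semicolon-joined keys) TSV profiles."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for row in frame.itertuples(index=False):
        keys = {k for k in str(row.substructures).split(";") if k}
        out[row.compound_id] = keys
    return out


def write_profiles(profiles: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"compound_id": cid, "substructures": ";".join(sorted(keys))}
        for cid, keys in sorted(profiles.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dictionary(path: str | Path) -> dict[str, str]:
    """Read a (key, pattern) TSV substructure dictionary."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_dictionary(dictionary: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"key": k, "pattern": v} for k, v in dictionary.items()]
    ).to_csv(path, sep="\t", index=False)


def write_edge_tsv(net: DTINetwork, path: str | Path) -> None:
    """Write (drug, target, provenance, aap_flag, gene_symbol) edges."""
    rows = []
    for drug, target, data in sorted(net.edges()):
        rows.append(
            {
                "drug": drug,
                "target": target,
                "provenance": ";".join(sorted(data["provenance"])),
                "aap_flag": int(net.is_aap_target(target)),
                "gene_symbol": net.target_gene(target) or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_tsv(path: str | Path) -> DTINetwork:
    """Load a network written by :func:`write_edge_tsv` (lossless)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    net = DTINetwork()
    for row in frame.itertuples(index=False):
        net.add_drug(row.drug)
        net.add_target(row.target, row.gene_symbol or None)
        for prov in str(row.provenance).split(";"):
            net.add_edge(row.drug, row.target, prov)
        net.graph.nodes[("target", row.target)]["aap"] = bool(int(row.aap_flag))
    return net


def write_graphml(net: DTINetwork, path: str | Path) -> None:
    """GraphML export with node (type, aap_flag, degree) and edge attributes."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    g = nx.Graph()
    for node, data in net.graph.nodes(data=True):
        kind, name = node
        attrs = {"type": kind, "degree": net.graph.degree(node)}
        if kind == "target":
            attrs["aap_flag"] = int(data.get("aap", False))
            attrs["gene_symbol"] = data.get("gene_symbol") or ""
        g.add_node(name, **attrs)
    for drug, target, data in net.edges():
        g.add_edge(drug, target, provenance=";".join(sorted(data["provenance"])))
    nx.write_graphml(g, str(path))


def warn_empty(kind: str) -> None:
    warnings.warn(f"empty {kind}; downstream results will be empty")


__all__ = [n for n in dir() if not n.startswith("_")]
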