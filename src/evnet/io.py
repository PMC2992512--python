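"""Readers and writers for the plain-text interchange formats.

* expression TSV: first column probe id, second gene id, remaining
  columns samples (header row of sample ids);
* sample-metadata TSV: sample_id, tissue, treatment, control_id;
* GMT: term, description, genes... (tab-separated, one term per line;
  the description field carries the term source tag);
* SIF: source, relation, target (directedness is declared by the
  caller, not the file);
* one-column universe file, EV-table TSV, promoter-class TSV,
  assignment TSV, ground-truth TSV, density-matrix TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import AnnotationSet, ExpressionMatrix, GeneNetwork
from .errors import ValidationError

SIF_RELATIONS = ("activates", "binds", "inhibits")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path, metadata_path=None) -> None:
    mapping = matrix.probe_to_gene or {p: p for p in matrix.values.index}
    out = matrix.values.copy()
    out.insert(0, "gene_id", [mapping.get(p, p) for p in out.index])
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        matrix.samples.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_expression_tsv(path, metadata_path=None, scale: str = "intensity") -> ExpressionMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "gene_id" not in table.columns:
        raise ValidationError(f"{path}: missing gene_id column")
    mapping = table["gene_id"].astype(str).to_dict()
    values = table.drop(columns=["gene_id"]).astype(float)
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0,
                           keep_default_na=False, dtype=str)
    return ExpressionMatrix(values, meta, scale, mapping)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_gmt(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations.terms):
            genes = "\t".join(sorted(annotations.terms[term]))
            fh.write(f"{term}\t{annotations.sources[term]}\t{genes}\n")


def read_gmt(path, universe=None) -> AnnotationSet:
    """Parse a GMT file. The description field is kept as the term source
    when it names one (``GO_style``/``pathway_style``), else GO_style.

    When no universe is supplied, the union of all term gene sets is
    used as the declared universe.
    """
    terms: dict = {}
    sources: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValidationError(f"{path}:{lineno}: term {term!r} has no genes")
            terms[term] = genes
            sources[term] = desc if desc in ("GO_style", "pathway_style") else "GO_style"
    if universe is None:
        universe = frozenset().union(*terms.values()) if terms else frozenset()
    return AnnotationSet(terms, frozenset(universe), sources)


def write_universe(universe, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(universe):
            fh.write(f"{g}\n")


def read_universe(path) -> frozenset:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_sif(network: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v, rel in sorted(network.edges):
            fh.write(f"{u}\t{rel}\t{v}\n")


def read_sif(path, directed: bool = False, provenance: str = "funnet") -> GeneNetwork:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: SIF line has {len(fields)} fields, needs 3"
                )
            u, rel, v = fields
            edges.append((u, v, rel))
    return GeneNetwork.from_edges(edges, directed=directed, provenance=provenance)


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------

def write_ev_table(ev: pd.DataFrame, path) -> None:
    ev.rename_axis("gene").to_csv(path, sep="\t")


def read_ev_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"ev", "mean_expr", "n_samples_used", "dataset_tag"} - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: EV table missing columns {sorted(missing)}")
    return table


def write_gene_map(mapping: dict, path, value_name: str) -> None:
    ser = pd.Series(mapping, name=value_name)
    ser.rename_axis("gene").sort_index().to_csv(path, sep="\t")


def read_gene_map(path, value_name: str) -> dict:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if value_name not in table.columns:
        raise ValidationError(f"{path}: missing column {value_name!r}")
    return table[value_name].to_dict()


def write_density(dm, path) -> None:
    dm.to_frame().rename_axis("bin").to_csv(path, sep="\t")
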