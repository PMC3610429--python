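"""Readers and writers for every external file the pipeline touches.

All formats are plain text: FASTA (protein/CDS), a gene-order TSV, orthogroup
files in two dialects (OrthoMCL-style ``groups`` text and pairwise TSV),
an hmmscan-domtblout-like domain-hit TSV, an expression TSV and the curated
factor-inventory TSV.  Every reader/writer pair round-trips losslessly on
valid data.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CANONICAL_TISSUES,
    STRANDS,
    DomainHit,
    ExpressionProfile,
    FactorEntry,
    FactorInventory,
    GenomeAnnotation,
    OrthologyGroups,
    warn,
)

# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]``.

    Order is preserved and ``'*'`` (stop) symbols are retained.  Duplicate
    ids are a hard error; an empty file yields an empty list with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warn(f"empty FASTA file: {path}")
        return []
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------- gene map

GENE_MAP_COLUMNS = ["gene_id", "species", "chromosome", "rank", "strand"]


def read_gene_map(path: str | Path) -> GenomeAnnotation:
    """Read the gene-order TSV into a :class:`GenomeAnnotation`.

    Within each (species, chromosome) the stated ranks must be unique; they
    are compacted to 0..n-1 preserving order (annotation rank gaps carry no
    information for a gene-count window).  Unknown strand symbols are stored
    as ``unknown`` with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in GENE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene map {path} missing columns: {missing}")
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        warn(
            f"{int(bad_strand.sum())} unknown strand symbols in {path}; "
            "stored as 'unknown'"
        )
    df["rank"] = df["rank"].astype(int)
    orders: dict[str, dict[str, list[str]]] = {}
    for (sp, chrom), sub in df.groupby(["species", "chromosome"], sort=True):
        ranks = sub["rank"].tolist()
        if len(set(ranks)) != len(ranks):
            dup = sorted({r for r in ranks if ranks.count(r) > 1})
            raise ValueError(
                f"duplicate rank(s) {dup} on {sp}:{chrom} in {path}"
            )
        sub = sub.sort_values("rank", kind="mergesort")
        orders.setdefault(sp, {})[chrom] = sub["gene_id"].tolist()
    return GenomeAnnotation(orders)


def write_gene_map(path: str | Path, annotation: GenomeAnnotation) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_MAP_COLUMNS)
        for row in annotation.as_rows():
            w.writerow(row)


# ---------------------------------------------------------------- groups

GROUP_DIALECTS = ("groups_text", "pair_tsv")


def read_groups(
    path: str | Path,
    dialect: str,
    method_id: str | None = None,
    separator: str = "|",
) -> OrthologyGroups:
    """Parse an orthogroup file.

    ``groups_text`` is the OrthoMCL convention ``NAME: sp|gene sp|gene ...``;
    ``pair_tsv`` is a two-column gene-pair list that is closed into groups by
    connected components (singletons are dropped).  Gene ids in ``pair_tsv``
    may carry a ``species|`` prefix; bare ids get species ``""``.
    """
    if dialect not in GROUP_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use one of {GROUP_DIALECTS}")
    mid = method_id or Path(path).stem
    if dialect == "groups_text":
        groups = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ValueError(f"{path}:{lineno}: missing ':' group header")
                _, _, body = line.partition(":")
                members = []
                for token in body.split():
                    if separator not in token:
                        raise ValueError(
                            f"{path}:{lineno}: token {token!r} lacks "
                            f"species separator {separator!r}"
                        )
                    sp, _, gid = token.partition(separator)
                    members.append((sp, gid))
                groups.append(members)
        return OrthologyGroups(mid, groups)

    graph: nx.Graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated genes")
            graph.add_edge(
                _split_member(parts[0], separator), _split_member(parts[1], separator)
            )
    return OrthologyGroups(mid, nx.connected_components(graph))


def _split_member(token: str, separator: str) -> tuple[str, str]:
    if separator in token:
        sp, _, gid = token.partition(separator)
        return sp, gid
    return "", token


def write_groups(
    path: str | Path, groups: OrthologyGroups, separator: str = "|"
) -> None:
    with open(path, "w") as fh:
        for i, g in enumerate(groups.groups, start=1):
            members = " ".join(
                f"{sp}{separator}{gid}" for sp, gid in sorted(g)
            )
            fh.write(f"GROUP{i}: {members}\n")


# ---------------------------------------------------------------- domain hits

DOMAIN_COLUMNS = ["gene_id", "domain_name", "start", "end", "score"]


def read_domain_table(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table {path} missing columns: {missing}")
    return [
        DomainHit(
            gene_id=str(r.gene_id),
            domain_name=str(r.domain_name),
            start=int(r.start),
            end=int(r.end),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def write_domain_table(path: str | Path, hits: Iterable[DomainHit]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DOMAIN_COLUMNS)
        for h in hits:
            w.writerow([h.gene_id, h.domain_name, h.start, h.end, h.score])


# ---------------------------------------------------------------- expression

PLATFORMS = ("microarray", "rnaseq")


def read_expression(path: str | Path) -> dict[str, ExpressionProfile]:
    """Read a gene x tissue expression TSV.

    The first line is a ``# platform=<tag>`` comment, the second the header
    row ``gene_id<TAB>tissue...`` with tissue labels from the canonical set.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# platform="):
            raise ValueError(f"{path}: missing '# platform=' header line")
        platform = first.split("=", 1)[1]
        if platform not in PLATFORMS:
            raise ValueError(f"{path}: unknown platform {platform!r}")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    tissues = tuple(df.columns)
    unknown = [t for t in tissues if t not in CANONICAL_TISSUES]
    if unknown:
        raise ValueError(f"{path}: non-canonical tissue labels {unknown}")
    out: dict[str, ExpressionProfile] = {}
    for gid, row in df.iterrows():
        out[str(gid)] = ExpressionProfile(
            gene_id=str(gid),
            platform=platform,
            values=tuple(float(v) for v in row.values),
            tissues=tissues,
        )
    return out


def write_expression(
    path: str | Path, profiles: Mapping[str, ExpressionProfile]
) -> None:
    profs = [profiles[g] for g in sorted(profiles)]
    if not profs:
        raise ValueError("nothing to write")
    platform = profs[0].platform
    tissues = profs[0].tissues
    with open(path, "w", newline="") as fh:
        fh.write(f"# platform={platform}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", *tissues])
        for p in profs:
            if p.platform != platform or p.tissues != tissues:
                raise ValueError("mixed platforms/tissues in one matrix")
            w.writerow([p.gene_id, *[repr(v) for v in p.values]])


# ---------------------------------------------------------------- inventory

INVENTORY_COLUMNS = ["factor_name", "compartment", "baits", "literature_only"]


def read_inventory(path: str | Path, separator: str = "|") -> FactorInventory:
    """Read the curated factor inventory TSV.

    ``baits`` is a comma-joined list of ``species|gene_id`` accessions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in INVENTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"inventory {path} missing columns: {missing}")
    entries = []
    for r in df.itertuples():
        baits = []
        for token in str(r.baits).split(","):
            token = token.strip()
            if not token:
                continue
            sp, _, gid = token.partition(separator)
            if not gid:
                raise ValueError(
                    f"inventory bait {token!r} lacks species separator"
                )
            baits.append((sp, gid))
        entries.append(
            FactorEntry(
                factor_name=str(r.factor_name),
                compartment=str(r.compartment),
                baits=baits,
                literature_only=str(r.literature_only).lower() in ("1", "true", "yes"),
            )
        )
    return FactorInventory(entries)


def write_inventory(
    path: str | Path, inventory: FactorInventory, separator: str = "|"
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(INVENTORY_COLUMNS)
        for e in inventory:
            baits = ",".join(f"{sp}{separator}{gid}" for sp, gid in e.baits)
            w.writerow(
                [e.factor_name, e.compartment, baits, str(e.literature_only).lower()]
            )


# ---------------------------------------------------------------- bundled data


def packaged_inventory_path() -> Path:
    """Path of the bundled literature factor inventory (synthetic baits)."""
    return Path(__file__).parent / "data" / "factor_inventory.synthetic.tsv"


def load_packaged_inventory() -> FactorInventory:
    return read_inventory(packaged_inventory_path())
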