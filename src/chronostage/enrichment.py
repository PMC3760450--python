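"""Gene-set over-representation by the cumulative hypergeometric test.

Probe-to-gene mapping follows the single-gene convention: only probes mapping
to exactly one gene contribute; multi-mapping and unmapped probes are
discarded.  For a query of n genes drawn from a population of N containing a
gene set of size K, the enrichment p value is the upper-tail probability
P(X >= k) of the observed overlap k under X ~ Hypergeometric(N, K, n) --
the tail includes the observed count.  BH FDR is applied within each
collection; gene-level collections should be tested against the gene-level
population and probe-level (array-derived) collections against the
probe-level population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .config import AnalysisConfig
from .diffexpr import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets plus a source tag (``gene`` or ``probe`` level)."""

    sets: dict[str, set[str]]
    source: str = "gene"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def map_probes_to_genes(
    probes: Iterable[str],
    mapping: pd.DataFrame | Mapping[str, Iterable[str]],
) -> tuple[list[str], int]:
    """Collapse a probe list to genes under the single-gene rule.

    ``mapping`` is either a DataFrame with ``probe_id``/``gene`` columns (one
    row per probe-gene pair) or a dict of probe -> iterable of genes.  Returns
    the de-duplicated gene list (input order of first occurrence) and the
    number of probes discarded for mapping to zero or multiple genes.
    """
    if isinstance(mapping, pd.DataFrame):
        lut: dict[str, list[str]] = {}
        for probe, gene in zip(mapping["probe_id"], mapping["gene"]):
            lut.setdefault(str(probe), []).append(str(gene))
    else:
        lut = {str(k): [str(g) for g in v] for k, v in mapping.items()}

    genes: list[str] = []
    seen: set[str] = set()
    discarded = 0
    for probe in probes:
        targets = set(lut.get(str(probe), ()))
        if len(targets) != 1:
            discarded += 1
            continue
        (gene,) = targets
        if gene not in seen:
            seen.add(gene)
            genes.append(gene)
    return genes, discarded


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    population: Iterable[str],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query list in each set.

    Every set is intersected with the population before testing.  Raises
    ``ValueError`` listing query genes absent from the population.  Returns a
    DataFrame sorted by p with columns ``N, K, n, k, p, q, significant``
    (BH FDR within the collection, flagged at ``fdr_enrich``).
    """
    config = config or AnalysisConfig()
    pop = set(map(str, population))
    q_set = set(map(str, query))
    offenders = sorted(q_set - pop)
    if offenders:
        raise ValueError(f"query genes absent from the population: {offenders[:10]}")

    sets = collection.sets if isinstance(collection, GeneSetCollection) else {
        k: set(map(str, v)) for k, v in collection.items()
    }
    N, n = len(pop), len(q_set)
    rows = []
    for name, members in sets.items():
        in_pop = set(members) & pop
        K = len(in_pop)
        k = len(q_set & in_pop)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k), observed included
        rows.append((name, N, K, n, k, p))
    out = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "p"]).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < config.fdr_enrich
    return out.sort_values("p")


def hypergeom_enrich_collections(
    collections: Mapping[str, GeneSetCollection],
    query: Iterable[str],
    populations: Mapping[str, Iterable[str]],
    config: AnalysisConfig | None = None,
    global_fdr: bool = False,
) -> pd.DataFrame:
    """Test several collections, each against its own population.

    ``populations`` maps a source tag (``gene`` / ``probe``) to the matching
    population.  By default BH FDR is applied within each collection
    (per-source reporting); ``global_fdr=True`` recomputes q across all
    collections jointly.
    """
    config = config or AnalysisConfig()
    frames = []
    for name, coll in collections.items():
        pop = populations[coll.source]
        res = hypergeom_enrich(query, coll, pop, config)
        res.insert(0, "collection", name)
        frames.append(res)
    out = pd.concat(frames)
    if global_fdr:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < config.fdr_enrich
    return out.sort_values("p")


def gene_list_table_to_gmt(
    table: pd.DataFrame, source: str = "gene"
) -> GeneSetCollection:
    """Convert a long-format gene-list export into a collection.

    Expected columns: ``set`` (term or cluster name), ``gene`` (member
    identifier) and optionally ``description``; one row per set-gene pair,
    the shape of a tabular export from an annotation database.  Live database
    queries are out of scope -- export the table, then convert.
    """
    for col in ("set", "gene"):
        if col not in table.columns:
            raise ValueError(f"expected a {col!r} column")
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for _, row in table.iterrows():
        sets.setdefault(str(row["set"]), set()).add(str(row["gene"]))
        if "description" in table.columns:
            descriptions.setdefault(str(row["set"]), str(row["description"]))
    return GeneSetCollection(sets=sets, source=source, descriptions=descriptions)


# ---------------------------------------------------------------------------
# GMT files (tab-delimited: set name, description, member genes)


def read_gmt(path: str | Path, source: str = "gene") -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, *members = fields
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = {m for m in members if m}
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, source=source, descriptions=descriptions)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")
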