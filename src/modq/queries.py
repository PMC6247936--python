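"""The five query families over modules, genomes and genes.

* genomes -> modules: completeness matrix (:func:`modq.completeness.genomes_to_modules`)
* module -> genomes: genomes complete above a threshold
* gene -> modules: modules that feature a gene
* genes -> genomes: presence of genes across genomes
* missing genes: what must be added for a module to be complete

All result orderings are deterministic (completeness descending, then
lexicographic) so outputs are diff-stable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .completeness import GeneSet, compute_mcf_pair, evaluate_node
from .errors import ApproximateCoverWarning, EmptyQuery, EmptySelection
from .grammar import (
    Alternatives,
    Complex,
    DefinitionAST,
    Gap,
    GeneToken,
    Leaf,
    Never,
    Node,
    OptionalNode,
    Sequence,
    leaf_tokens,
)
from .kegg_io import GenomeRecord, ModuleRecord

__all__ = [
    "select_modules",
    "module_to_genomes",
    "gene_to_modules",
    "genes_to_genomes",
    "CompletionSet",
    "missing_genes",
    "EXACT_LEAF_CAP",
]

#: Above this many leaves in a module, the overall completion set is found
#: greedily rather than by exact search (flagged ``approximate``).
EXACT_LEAF_CAP = 20


def select_modules(
    module_db: list[ModuleRecord],
    by_id: list[str] | None = None,
    by_name_substring: str | None = None,
    by_class_substring: str | None = None,
) -> list[ModuleRecord]:
    """Select modules by identifier, name substring and/or class substring.

    Criteria are unioned; substring matching is case-insensitive.  With no
    criteria every module is returned (the default scope of all queries).
    """
    if not by_id and not by_name_substring and not by_class_substring:
        return list(module_db)
    ids = set(by_id or [])
    name_sub = (by_name_substring or "").lower()
    class_sub = (by_class_substring or "").lower()
    out = []
    for mod in module_db:
        hit = mod.module_id in ids
        if not hit and name_sub:
            hit = name_sub in mod.name.lower()
        if not hit and class_sub:
            hit = any(class_sub in lvl.lower() for lvl in mod.class_levels)
        if hit:
            out.append(mod)
    return out


def module_to_genomes(
    modules: list[ModuleRecord],
    genome_db: list[GenomeRecord],
    threshold: float = 1.0,
    *,
    count_gaps: str = "excluded",
) -> dict[str, list[tuple[str, float]]]:
    """Genomes whose completeness for each module meets ``threshold``.

    Default threshold 1 returns only genomes with the module complete.
    Results are sorted by completeness descending, then genome id.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if not modules:
        raise EmptySelection("no modules selected")
    out: dict[str, list[tuple[str, float]]] = {}
    for mod in modules:
        hits = []
        for genome in genome_db:
            mcf = compute_mcf_pair(
                mod.ast, genome.genes, count_gaps=count_gaps
            ).value
            if mcf >= threshold:
                hits.append((genome.genome_id, mcf))
        hits.sort(key=lambda t: (-t[1], t[0]))
        out[mod.module_id] = hits
    return out


def gene_to_modules(
    genes: list[GeneToken], module_db: list[ModuleRecord]
) -> dict[GeneToken, list[str]]:
    """Modules that feature each query gene (optional subunits included)."""
    out: dict[GeneToken, list[str]] = {}
    for gene in genes:
        if gene in out:
            continue  # deduplicate query genes
        out[gene] = sorted(
            m.module_id for m in module_db if gene in leaf_tokens(m.ast)
        )
    return out


def genes_to_genomes(
    genes: list[GeneToken], genome_db: list[GenomeRecord]
) -> pd.DataFrame:
    """Binary presence of the query genes across genomes.

    Returns a genomes-by-genes 0/1 table with a trailing ``n_present``
    column counting how many query genes each genome carries.
    """
    if not genes:
        raise EmptyQuery("no query genes given")
    uniq: list[GeneToken] = []
    for g in genes:
        if g not in uniq:
            uniq.append(g)
    rows = {}
    for genome in genome_db:
        rows[genome.genome_id] = [int(g in genome.genes) for g in uniq]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[g.identifier for g in uniq]
    )
    df["n_present"] = df.sum(axis=1)
    return df


# --------------------------------------------------------------------------
# Missing genes


@dataclass
class CompletionSet:
    """Genes that would complete a module for a given gene set.

    ``per_block`` maps the index of each unsatisfied block (0-based over
    the definition's top-level blocks) to every inclusion-minimal token
    set whose addition satisfies that block.  ``overall`` is one
    minimum-cardinality union across blocks; adding it to the query gene
    set makes the module complete.  ``approximate`` flags a greedy (not
    exact) overall search.
    """

    module_id: str
    per_block: dict[int, list[frozenset[GeneToken]]] = field(default_factory=dict)
    overall: frozenset[GeneToken] = frozenset()
    approximate: bool = False

    @property
    def complete(self) -> bool:
        return not self.per_block


def _required_leaves(node: Node) -> set[GeneToken]:
    """Leaves that can contribute to satisfying a node; optional subtrees
    are excluded (they are never required, hence never missing)."""
    if isinstance(node, Leaf):
        return {node.token}
    if isinstance(node, (Gap, Never, OptionalNode)):
        return set()
    if isinstance(node, (Alternatives, Complex, Sequence)):
        out: set[GeneToken] = set()
        for child in node.children:
            out |= _required_leaves(child)
        return out
    raise TypeError(f"unknown node {node!r}")


def _cheapest_set(node: Node, genes: GeneSet) -> frozenset[GeneToken] | None:
    """One small (not necessarily minimum) token set satisfying ``node``
    on top of ``genes``; None when the node is unsatisfiable."""
    if isinstance(node, Leaf):
        if evaluate_node(node, genes):
            return frozenset()
        return frozenset({node.token})
    if isinstance(node, (Gap, OptionalNode)):
        return frozenset()
    if isinstance(node, Never):
        return None
    if isinstance(node, Alternatives):
        best = None
        for child in node.children:
            cand = _cheapest_set(child, genes)
            if cand is None:
                continue
            key = (len(cand), sorted(t.identifier for t in cand))
            if best is None or key < best[0]:
                best = (key, cand)
        return best[1] if best else None
    if isinstance(node, (Complex, Sequence)):
        total: set[GeneToken] = set()
        for child in node.children:
            cand = _cheapest_set(child, genes)
            if cand is None:
                return None
            total |= cand
        return frozenset(total)
    raise TypeError(f"unknown node {node!r}")


def _minimal_block_sets(
    block: Node, genes: GeneSet
) -> list[frozenset[GeneToken]]:
    """All inclusion-minimal sets of absent required tokens whose addition
    satisfies the block, by exhaustive subset search."""
    candidates = sorted(
        (t for t in _required_leaves(block) if not evaluate_node(Leaf(t), genes)),
        key=lambda t: t.identifier,
    )
    minimal: list[frozenset[GeneToken]] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            s = frozenset(combo)
            if any(kept <= s for kept in minimal):
                continue
            if evaluate_node(block, genes.union(s)):
                minimal.append(s)
        if size == 0 and minimal:
            break  # block was already satisfied (shouldn't happen here)
    return minimal


def _sorted_ids(tokens: frozenset[GeneToken]) -> tuple[str, ...]:
    return tuple(sorted(t.identifier for t in tokens))


def missing_genes(
    module: ModuleRecord,
    genes: GeneSet,
    *,
    count_gaps: str = "excluded",
    exact_leaf_cap: int = EXACT_LEAF_CAP,
) -> CompletionSet:
    """Determine which genes are missing for a module to be complete.

    For every unsatisfied block all inclusion-minimal completing token
    sets are enumerated; the ``overall`` completion is a
    minimum-cardinality union of one choice per block, found exactly while
    the module has at most ``exact_leaf_cap`` leaves and greedily beyond
    (flagged approximate, with a warning).  Optional subunits are never
    proposed.  Ties break lexicographically.
    """
    ast: DefinitionAST = module.ast
    n_leaves = len(leaf_tokens(ast))
    exact = n_leaves <= exact_leaf_cap
    per_block: dict[int, list[frozenset[GeneToken]]] = {}
    for idx, block in enumerate(ast.root.children):
        if isinstance(block, Gap):
            continue
        if evaluate_node(block, genes):
            continue
        if exact:
            per_block[idx] = sorted(
                _minimal_block_sets(block, genes), key=_sorted_ids
            )
        else:
            cheap = _cheapest_set(block, genes)
            per_block[idx] = [cheap] if cheap is not None else []
    if not per_block:
        return CompletionSet(module.module_id)
    block_choices = list(per_block.values())
    unsatisfiable = [i for i, c in zip(per_block, block_choices) if not c]
    if unsatisfiable:
        # blocks reduced to Never sentinels cannot be completed
        overall: frozenset[GeneToken] = frozenset().union(
            *(min(c, key=lambda s: (len(s), _sorted_ids(s))) for c in block_choices if c)
        ) if any(block_choices) else frozenset()
        return CompletionSet(module.module_id, per_block, overall, approximate=True)

    n_combos = 1
    for choices in block_choices:
        n_combos *= len(choices)
    if exact and n_combos <= 100_000:
        best: tuple[tuple[int, tuple[str, ...]], frozenset[GeneToken]] | None = None
        for combo in itertools.product(*block_choices):
            union = frozenset().union(*combo)
            key = (len(union), _sorted_ids(union))
            if best is None or key < best[0]:
                best = (key, union)
        overall = best[1]
        approximate = False
    else:
        chosen: set[GeneToken] = set()
        for choices in block_choices:
            pick = min(
                choices,
                key=lambda s: (len(s - chosen), _sorted_ids(s - chosen)),
            )
            chosen |= pick
        overall = frozenset(chosen)
        approximate = True
        warnings.warn(
            f"module {module.module_id}: overall completion found greedily",
            ApproximateCoverWarning,
            stacklevel=2,
        )
    return CompletionSet(module.module_id, per_block, overall, approximate)
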