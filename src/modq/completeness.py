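"""Block evaluation and the module completeness fraction (mcf).

The mcf of a gene set against a module definition is the number of
satisfied top-level blocks divided by the number of blocks.  Satisfaction
is binary per block; the fraction is therefore always a ratio of two small
integers, which this module tracks exactly (see :class:`MCF`) and emits as
a float.

Enzyme-namespace matching supports EC wildcards: a *requirement*
``1.1.1.-`` is a family and is satisfied by any annotated ``1.1.1.x``,
while an *annotation* ``1.1.1.-`` expresses uncertainty and does not
satisfy the specific requirement ``1.1.1.1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence as TSequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDefinitionWarning,
    EmptySelection,
    NamespaceMismatch,
)
from .grammar import (
    Alternatives,
    Complex,
    DefinitionAST,
    Gap,
    GeneToken,
    Leaf,
    Namespace,
    Never,
    Node,
    OptionalNode,
    Sequence,
)

if TYPE_CHECKING:  # pragma: no cover
    from .kegg_io import ModuleRecord

__all__ = [
    "GeneSet",
    "MCF",
    "MCFMatrix",
    "ec_satisfies",
    "evaluate_node",
    "compute_mcf",
    "compute_mcf_pair",
    "genomes_to_modules",
]


@dataclass(frozen=True)
class GeneSet:
    """A set of gene identifiers in a single namespace."""

    namespace: Namespace
    members: frozenset[GeneToken] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for tok in self.members:
            if tok.namespace is not self.namespace:
                raise NamespaceMismatch(
                    f"token {tok.identifier} is {tok.namespace.value}, "
                    f"gene set is {self.namespace.value}"
                )

    @classmethod
    def from_identifiers(
        cls, identifiers: Iterable[str], namespace: Namespace | None = None
    ) -> "GeneSet":
        toks = [GeneToken.of(i, namespace) for i in identifiers]
        if namespace is None:
            if not toks:
                raise ValueError("cannot infer namespace from an empty set")
            namespace = toks[0].namespace
            for t in toks:
                if t.namespace is not namespace:
                    raise NamespaceMismatch(
                        "mixed K and EC identifiers in one gene set"
                    )
        return cls(namespace, frozenset(toks))

    @classmethod
    def from_file(
        cls, path, namespace: Namespace | None = None
    ) -> "GeneSet":
        """Read a plain-text gene list: one identifier per line, ``#``
        comments and blank lines ignored."""
        ids: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    ids.append(line)
        return cls.from_identifiers(ids, namespace)

    def __contains__(self, token: GeneToken) -> bool:
        return token in self.members

    def __len__(self) -> int:
        return len(self.members)

    def union(self, tokens: Iterable[GeneToken]) -> "GeneSet":
        return GeneSet(self.namespace, self.members | frozenset(tokens))


def ec_satisfies(requirement: str, annotation: str) -> bool:
    """Whether an annotated EC number satisfies a required one.

    Component-wise comparison: a ``-`` (or absent) component in the
    requirement matches anything; a numeric requirement component must be
    matched exactly, so a dash in the annotation never satisfies a numeric
    requirement.
    """
    req = requirement.split(".")
    ann = annotation.split(".")
    depth = max(len(req), len(ann))
    req += ["-"] * (depth - len(req))
    ann += ["-"] * (depth - len(ann))
    for r, a in zip(req, ann):
        if r == "-":
            continue
        if r != a:
            return False
    return True


def _leaf_satisfied(
    token: GeneToken, genes: GeneSet, ec_wildcards: bool
) -> bool:
    if token.namespace is not genes.namespace:
        raise NamespaceMismatch(
            f"definition token {token.identifier} is "
            f"{token.namespace.value}, gene set is {genes.namespace.value}"
        )
    if token in genes:
        return True
    if ec_wildcards and token.namespace is Namespace.ENZYME and "-" in token.identifier:
        return any(
            ec_satisfies(token.identifier, m.identifier) for m in genes.members
        )
    return False


def evaluate_node(
    node: Node, genes: GeneSet, *, ec_wildcards: bool = True
) -> bool:
    """Evaluate satisfaction of one expression-tree node.

    Leaf: token present (EC wildcards in the requirement match family
    members when ``ec_wildcards``).  Alternatives: any child.  Complex and
    Sequence: all non-optional children.  Optional: always satisfied.
    Gap: always satisfied.  Never: never satisfied.
    """
    if isinstance(node, Leaf):
        return _leaf_satisfied(node.token, genes, ec_wildcards)
    if isinstance(node, Never):
        return False
    if isinstance(node, (Gap, OptionalNode)):
        return True
    if isinstance(node, Alternatives):
        return any(
            evaluate_node(c, genes, ec_wildcards=ec_wildcards)
            for c in node.children
        )
    if isinstance(node, (Complex, Sequence)):
        return all(
            evaluate_node(c, genes, ec_wildcards=ec_wildcards)
            for c in node.children
        )
    raise TypeError(f"unknown node {node!r}")


@dataclass(frozen=True)
class MCF:
    """Exact module completeness fraction as an integer pair."""

    satisfied: int
    total: int

    @property
    def value(self) -> float:
        if self.total == 0:
            return 1.0  # degenerate: no countable block demands a gene
        return self.satisfied / self.total

    def __float__(self) -> float:
        return self.value


def compute_mcf_pair(
    ast: DefinitionAST,
    genes: GeneSet,
    *,
    count_gaps: str = "excluded",
    ec_wildcards: bool = True,
) -> MCF:
    """Count satisfied and total blocks for a gene set against a module.

    Gap blocks are excluded from both counts by default
    (``count_gaps="as-satisfied"`` counts them as satisfied instead).  A
    definition whose blocks are all gaps has no countable requirement; its
    completeness is defined as 1 and a
    :class:`~modq.errors.DegenerateDefinitionWarning` is emitted.
    """
    if count_gaps not in ("excluded", "as-satisfied"):
        raise ValueError(f"count_gaps={count_gaps!r}")
    satisfied = total = 0
    for block in ast.root.children:
        if isinstance(block, Gap):
            if count_gaps == "as-satisfied":
                satisfied += 1
                total += 1
            continue
        total += 1
        if evaluate_node(block, genes, ec_wildcards=ec_wildcards):
            satisfied += 1
    if total == 0:
        warnings.warn(
            "definition has no countable blocks; completeness defined as 1",
            DegenerateDefinitionWarning,
            stacklevel=2,
        )
    return MCF(satisfied, total)


def compute_mcf(
    ast: DefinitionAST,
    genes: GeneSet,
    *,
    count_gaps: str = "excluded",
    ec_wildcards: bool = True,
) -> float:
    """Module completeness fraction in [0, 1]; 1 means complete."""
    return compute_mcf_pair(
        ast, genes, count_gaps=count_gaps, ec_wildcards=ec_wildcards
    ).value


class MCFMatrix:
    """Gene sets (rows) by modules (columns) matrix of completeness
    fractions.

    Natively built from exact integer pairs (kept for exact zero-variance
    and equality checks); matrices loaded from TSV carry floats only.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        satisfied: pd.DataFrame | None = None,
        total: pd.DataFrame | None = None,
    ):
        values = values.astype(float)
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("row and column labels must be unique")
        arr = values.to_numpy()
        if arr.size and ((arr < 0) | (arr > 1)).any():
            raise ValueError("completeness fractions must lie in [0, 1]")
        self._values = values
        if (satisfied is None) != (total is None):
            raise ValueError("satisfied and total must be given together")
        self._satisfied = satisfied
        self._total = total

    @classmethod
    def from_pairs(
        cls, satisfied: pd.DataFrame, total: pd.DataFrame
    ) -> "MCFMatrix":
        sat = satisfied.astype(int)
        tot = total.astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = sat / tot
        vals = vals.where(tot != 0, 1.0)
        return cls(vals, sat, tot)

    # -- container protocol -------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        """Float view (copy-safe reference) of the matrix."""
        return self._values

    @property
    def pairs(self) -> tuple[pd.DataFrame, pd.DataFrame] | None:
        """Exact (satisfied, total) integer frames when natively computed."""
        if self._satisfied is None:
            return None
        return self._satisfied, self._total

    @property
    def row_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MCFMatrix):
            return NotImplemented
        return self._values.equals(other._values)

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV with row labels in the first column."""
        self._values.to_csv(path, sep="\t", index_label="label")

    @classmethod
    def from_tsv(cls, path) -> "MCFMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


def genomes_to_modules(
    gene_sets: Mapping[str, GeneSet],
    modules: TSequence["ModuleRecord"],
    *,
    count_gaps: str = "excluded",
    ec_wildcards: bool = True,
) -> MCFMatrix:
    """Compute the mcf matrix for labelled gene sets against modules.

    One row per gene set (insertion order), one column per module.  Module
    selection by id/name/class is done upstream with
    :func:`modq.queries.select_modules`.
    """
    if not modules:
        raise EmptySelection("no modules to evaluate")
    labels = list(gene_sets)
    module_ids = [m.module_id for m in modules]
    sat = np.zeros((len(labels), len(modules)), dtype=int)
    tot = np.zeros_like(sat)
    with warnings.catch_warnings():
        # degenerate modules warn once per matrix, not per cell
        warnings.simplefilter("once", DegenerateDefinitionWarning)
        for i, label in enumerate(labels):
            genes = gene_sets[label]
            for j, mod in enumerate(modules):
                pair = compute_mcf_pair(
                    mod.ast,
                    genes,
                    count_gaps=count_gaps,
                    ec_wildcards=ec_wildcards,
                )
                sat[i, j] = pair.satisfied
                tot[i, j] = pair.total
    return MCFMatrix.from_pairs(
        pd.DataFrame(sat, index=labels, columns=module_ids),
        pd.DataFrame(tot, index=labels, columns=module_ids),
    )
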