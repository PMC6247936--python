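"""Synthetic KEGG-dialect fixture databases with known ground truth.

Real KEGG data is licence-restricted, so everything in this package is
exercised against generated module, genome and mapping files written in
the same dialects.  The generator controls the completeness of every
(genome, module) pair exactly: a genome receives a full satisfying gene
selection for exactly ``k`` of a module's countable blocks (and at most a
strict, non-satisfying subset for the others), so the engine must
reproduce the emitted ground-truth table k/n for k/n.

Every leaf of every generated definition is a fresh K number (token pools
are disjoint across blocks and modules), which makes non-satisfaction of
withheld blocks structural; the generator still re-verifies every target
with the completeness engine and resamples a genome on any collision.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .completeness import GeneSet, MCFMatrix, compute_mcf_pair, evaluate_node
from .errors import UnachievableTarget
from .grammar import (
    Alternatives,
    Complex,
    DefinitionAST,
    Gap,
    GeneToken,
    Leaf,
    Namespace,
    Node,
    OptionalNode,
    Sequence,
    parse_definition,
    render_definition,
)
from .kegg_io import (
    GenomeRecord,
    ModuleRecord,
    write_genome_db,
    write_list_file,
    write_module_db,
)
from .translate import MappingTable

__all__ = [
    "FixtureSpec",
    "generate_module_db",
    "generate_genomes",
    "generate_mapping",
    "generate_fixture_set",
]

_CLASS_TAXONOMY = [
    ("Pathway modules", "Energy metabolism"),
    ("Pathway modules", "Carbohydrate metabolism"),
    ("Pathway modules", "Amino acid metabolism"),
    ("Signature modules", "Metabolic capacity"),
]

_GENERA = ["Alphagenus", "Betagenus", "Gammagenus", "Deltagenus"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture database.

    Defaults give a desk-scale database: 10 modules of 2-5 blocks over
    the full definition grammar and 20 genomes with uniformly drawn
    block-count targets.  A fixed seed makes all outputs byte-identical
    across runs.
    """

    n_modules: int = 10
    blocks_min: int = 2
    blocks_max: int = 5
    p_alternatives: float = 0.30
    p_complex: float = 0.25
    p_nested: float = 0.10
    p_optional: float = 0.15
    p_gap: float = 0.05
    n_genomes: int = 20
    seed: int = 0
    #: optional explicit targets: genome label -> module id -> fraction.
    target_profile: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        for name in ("p_alternatives", "p_complex", "p_nested",
                     "p_optional", "p_gap"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.blocks_min < 1 or self.blocks_max < self.blocks_min:
            raise ValueError("invalid block count range")


class _TokenAllocator:
    """Fresh, globally unique K numbers."""

    def __init__(self) -> None:
        self.counter = 0

    def __call__(self) -> GeneToken:
        self.counter += 1
        return GeneToken(Namespace.ORTHOLOG, f"K{self.counter:05d}")


def _sample_atom(rng: random.Random, alloc: _TokenAllocator,
                 spec: FixtureSpec, depth: int) -> Node:
    if depth < 2 and rng.random() < spec.p_complex / 2:
        return _sample_complex(rng, alloc, spec, depth + 1)
    return Leaf(alloc())


def _sample_complex(rng: random.Random, alloc: _TokenAllocator,
                    spec: FixtureSpec, depth: int) -> Node:
    n = rng.randint(2, 3)
    children: list[Node] = [Leaf(alloc()) for _ in range(n)]
    # mark at most n-1 subunits optional so the complex keeps a requirement
    for i in range(1, n):
        if rng.random() < spec.p_optional:
            children[i] = OptionalNode(children[i])
    return Complex(tuple(children))


def _sample_block(rng: random.Random, alloc: _TokenAllocator,
                  spec: FixtureSpec) -> Node:
    r = rng.random()
    if r < spec.p_gap:
        return Gap()
    r = rng.random()
    if r < spec.p_alternatives:
        n = rng.randint(2, 3)
        return Alternatives(
            tuple(_sample_atom(rng, alloc, spec, 1) for _ in range(n))
        )
    if r < spec.p_alternatives + spec.p_complex:
        return _sample_complex(rng, alloc, spec, 1)
    if r < spec.p_alternatives + spec.p_complex + spec.p_nested:
        # parenthesized conjunction of two sub-steps inside one block
        return Sequence(
            tuple(_sample_atom(rng, alloc, spec, 1) for _ in range(2))
        )
    return Leaf(alloc())


def generate_module_db(
    spec: FixtureSpec, outdir: str | Path | None = None
) -> list[ModuleRecord]:
    """Generate synthetic modules; write the flat file when ``outdir`` is
    given.  Every emitted definition round-trips through parse/render."""
    rng = random.Random(spec.seed)
    alloc = _TokenAllocator()
    modules: list[ModuleRecord] = []
    for i in range(spec.n_modules):
        n_blocks = rng.randint(spec.blocks_min, spec.blocks_max)
        blocks = [_sample_block(rng, alloc, spec) for _ in range(n_blocks)]
        if all(isinstance(b, Gap) for b in blocks):
            blocks[0] = Leaf(alloc())  # keep at least one countable block
        ast = DefinitionAST(Sequence(tuple(blocks)), Namespace.ORTHOLOG)
        text = render_definition(ast)
        reparsed = parse_definition(text, Namespace.ORTHOLOG)
        assert reparsed == ast, "generated definition must round-trip"
        level1, level2 = _CLASS_TAXONOMY[i % len(_CLASS_TAXONOMY)]
        modules.append(
            ModuleRecord(
                module_id=f"MFX{i + 1:03d}",
                name=f"Synthetic pathway segment {i + 1}",
                class_levels=[level1, level2],
                definition_text=text,
                ast=ast,
            )
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_module_db(modules, outdir / "module")
    return modules


def _satisfying_selection(node: Node, rng: random.Random) -> set[GeneToken]:
    """A gene selection satisfying ``node`` (one alternative chosen at
    random; optional subunits occasionally included)."""
    if isinstance(node, Leaf):
        return {node.token}
    if isinstance(node, Gap):
        return set()
    if isinstance(node, OptionalNode):
        if rng.random() < 0.3:
            return _satisfying_selection(node.child, rng)
        return set()
    if isinstance(node, Alternatives):
        return _satisfying_selection(rng.choice(node.children), rng)
    if isinstance(node, (Complex, Sequence)):
        out: set[GeneToken] = set()
        for child in node.children:
            out |= _satisfying_selection(child, rng)
        return out
    raise TypeError(f"unknown node {node!r}")


def _distractor_subset(block: Node, rng: random.Random) -> set[GeneToken]:
    """A strict subset of a satisfying selection that does NOT satisfy the
    block (possibly empty): realistic partial pathways."""
    full = sorted(_satisfying_selection(block, rng), key=lambda t: t.identifier)
    if len(full) < 2 or rng.random() < 0.5:
        return set()
    subset = set(rng.sample(full, len(full) - 1))
    probe = GeneSet(Namespace.ORTHOLOG, frozenset(subset))
    if evaluate_node(block, probe):
        return set()  # e.g. the dropped token was optional
    return subset


def _target_blocks(module: ModuleRecord) -> list[Node]:
    return [b for b in module.ast.root.children if not isinstance(b, Gap)]


def _resolve_target(fraction: float, n_blocks: int) -> int:
    k = fraction * n_blocks
    if abs(k - round(k)) > 1e-9:
        raise UnachievableTarget(
            f"target {fraction} is not k/{n_blocks} for any integer k"
        )
    return int(round(k))


def generate_genomes(
    modules: list[ModuleRecord],
    spec: FixtureSpec,
    outdir: str | Path | None = None,
) -> tuple[list[GenomeRecord], MCFMatrix]:
    """Generate genomes engineered to hit exact completeness targets.

    Returns the genome records and the ground-truth completeness matrix
    (with exact integer pairs).  When ``outdir`` is given, writes the
    genome flat file, the genome-to-ortholog ``.list``, the ground-truth
    TSV and a genus factor table.
    """
    rng = random.Random(spec.seed + 1)
    genomes: list[GenomeRecord] = []
    sat_rows, tot_rows = [], []
    labels = []
    for g in range(spec.n_genomes):
        gid = f"T{90001 + g}"
        genus = _GENERA[g % len(_GENERA)]
        for attempt in range(10):
            members: set[GeneToken] = set()
            sat_row, tot_row = [], []
            for mod in modules:
                blocks = _target_blocks(mod)
                n = len(blocks)
                if spec.target_profile is not None:
                    frac = spec.target_profile.get(gid, {}).get(
                        mod.module_id, 0.0
                    )
                    k = _resolve_target(frac, n)
                else:
                    k = rng.randint(0, n)
                chosen = rng.sample(range(n), k)
                for idx, block in enumerate(blocks):
                    if idx in chosen:
                        members |= _satisfying_selection(block, rng)
                    else:
                        members |= _distractor_subset(block, rng)
                sat_row.append(k)
                tot_row.append(n)
            genes = GeneSet(Namespace.ORTHOLOG, frozenset(members))
            # post-hoc verification against the engine (defensive: token
            # pools are disjoint, but shared-token fixtures would need it)
            ok = all(
                compute_mcf_pair(mod.ast, genes).satisfied == sat_row[j]
                for j, mod in enumerate(modules)
            )
            if ok:
                break
        else:
            raise UnachievableTarget(
                f"could not realize targets for genome {gid}"
            )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                organism_name=f"{genus} fixturensis {g + 1}",
                taxonomy=["Bacteria", genus],
                genes=genes,
            )
        )
        labels.append(gid)
        sat_rows.append(sat_row)
        tot_rows.append(tot_row)
    module_ids = [m.module_id for m in modules]
    truth = MCFMatrix.from_pairs(
        pd.DataFrame(sat_rows, index=labels, columns=module_ids),
        pd.DataFrame(tot_rows, index=labels, columns=module_ids),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_db(genomes, outdir / "genome", outdir / "genome_ko.list")
        truth.to_tsv(outdir / "ground_truth_mcf.tsv")
        with open(outdir / "factors.tsv", "w", encoding="utf-8") as fh:
            fh.write("label\tgenus\n")
            for g in genomes:
                fh.write(f"{g.genome_id}\t{g.taxonomy[-1]}\n")
    return genomes, truth


def generate_mapping(
    modules: list[ModuleRecord],
    fanout: int | tuple[int, int] = 1,
    unmapped_fraction: float = 0.0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> MappingTable:
    """Generate a K-to-EC mapping covering all module tokens.

    ``fanout`` (an int or an inclusive range) controls how many distinct
    EC numbers each mapped K receives; ``unmapped_fraction`` leaves that
    share of K numbers without any image.  EC numbers are globally unique
    across the mapping.
    """
    rng = random.Random(seed + 2)
    lo, hi = (fanout, fanout) if isinstance(fanout, int) else fanout
    if lo < 1:
        raise ValueError("fanout must be at least 1")
    all_k = sorted(
        {
            tok.identifier
            for mod in modules
            for tok in _iter_all_tokens(mod.ast)
        }
    )
    n_unmapped = int(round(unmapped_fraction * len(all_k)))
    unmapped = set(rng.sample(all_k, n_unmapped))
    pairs: set[tuple[str, str]] = set()
    counter = 0
    for k in all_k:
        if k in unmapped:
            continue
        for _ in range(rng.randint(lo, hi)):
            counter += 1
            ec = f"{(counter - 1) // 1000 + 1}.{(counter - 1) // 100 % 10 + 1}.{(counter - 1) // 10 % 10 + 1}.{(counter - 1) % 10 + 1}"
            pairs.add((k, ec))
    mapping = MappingTable("ko", "ec", frozenset(pairs))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_list_file(
            mapping, outdir / "ko_enzyme.list", from_prefix="ko", to_prefix="ec"
        )
    return mapping


def _iter_all_tokens(ast: DefinitionAST):
    from .grammar import leaf_tokens

    return leaf_tokens(ast)


def generate_fixture_set(
    spec: FixtureSpec, outdir: str | Path
) -> tuple[list[ModuleRecord], list[GenomeRecord], MCFMatrix, MappingTable]:
    """Generate a complete fixture directory laid out like a miniature
    database dump: module and genome flat files, genome-to-ortholog and
    K-to-EC ``.list`` files, the ground-truth completeness table and a
    genus factor table."""
    modules = generate_module_db(spec, outdir)
    genomes, truth = generate_genomes(modules, spec, outdir)
    mapping = generate_mapping(modules, fanout=(1, 3), seed=spec.seed, outdir=outdir)
    return modules, genomes, truth, mapping
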