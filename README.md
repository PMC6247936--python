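# modq

Query-based analysis of metabolic module completeness in genomes and gene
sets.

Microbial genomes are routinely annotated with KEGG Orthology identifiers
(K numbers) or Enzyme Commission numbers (EC numbers). KEGG *modules*
group these genes into functional units — pathway segments, transport
systems, biosynthetic routes — each defined by a logical expression over
gene identifiers. `modq` parses those definitions, scores how complete
each module is in a genome or gene set, and provides the query, analysis
and plotting layer needed to compare the metabolic capacity of many
genomes at once. It is aimed at microbial ecologists, metabolic engineers
and synthetic biologists who want systematic, scriptable answers to
questions like "which genomes can run this pathway?", "which modules does
this gene participate in?" and "what is missing for this organism to
complete this module?".

## The completeness model

A module definition is an ordered sequence of *blocks* (reaction steps)
separated by spaces. Within a block, `,` separates interchangeable
alternatives (OR), `+` joins subunits of a complex that must all be
present (AND), `-X` marks subunit `X` optional, `--` is a gap step with
no gene requirement, and parentheses group (a space inside parentheses is
a conjunction of sub-steps, not a new block).

For a gene set *G* and a module with blocks *b₁ … bₙ*, the **module
completeness fraction** is

&nbsp;&nbsp;&nbsp;&nbsp;mcf = (number of blocks satisfied by *G*) / *n*

where block satisfaction is the Boolean evaluation of its expression and
gap blocks are excluded from both counts (configurable). The mcf is
always a ratio of two small integers; `modq` tracks the exact pair and
emits the float. Because the grammar has no negation, mcf is monotone:
adding genes never lowers it.

Definitions written over K numbers can be translated to EC-number
definitions through a K→EC mapping: each leaf becomes the OR of its
enzyme images, preserving the block structure.

The analysis layer summarizes a genomes × modules mcf matrix: per-module
standard deviations, zero-variance modules, factor-grouped means, a
principal-component decomposition, and the mean pairwise Euclidean
distance Σᵢ<ⱼ d(xᵢ,xⱼ) / (p(p−1)/2) as a within-group spread proxy.

No KEGG data is bundled or downloaded (the real database is
licence-restricted): a synthetic fixture generator emits module, genome
and mapping files in the same flat-file dialects with exactly known
ground-truth completeness, which is what the test suite runs on. Users
with licensed KEGG FTP access can point the same readers at their own
files.

## Worked example

Score a gene set against a three-block module (a two-subunit complex,
an alternative pair, and a parenthesized two-step conjunction):

```python
from modq import (GeneSet, parse_definition, count_blocks,
                  compute_mcf_pair, missing_genes, ModuleRecord)

ast = parse_definition("K00200+K00201 K00320,K00577 (K00125 K00126)")
print("blocks:", count_blocks(ast))

genes = GeneSet.from_identifiers(["K00200", "K00201", "K00577"])
pair = compute_mcf_pair(ast, genes)
print("mcf:", pair.satisfied, "/", pair.total, "=", round(pair.value, 4))
```

```
blocks: 3
mcf: 2 / 3 = 0.6667
```

The complex block is satisfied (both subunits present), the alternative
block is satisfied through K00577, and the third block fails because
neither K00125 nor K00126 is annotated. Asking what is missing:

```python
mod = ModuleRecord("MFX001", "demo", ["Pathway modules"], "...", ast)
cs = missing_genes(mod, genes)
print(sorted(t.identifier for t in cs.overall))
```

```
['K00125', 'K00126']
```

— the unique minimal completion: both genes of the conjunctive step.

The same works at scale from the shell. Generate a synthetic database
and compute the full mcf matrix:

```bash
modq fixtures generate --out fx --seed 1 --n-modules 5 --n-genomes 6
modq genomes-to-modules --modules-db fx/module \
    --genome-db fx/genome --genome-ko fx/genome_ko.list --out out
head -4 out/mcf.tsv
```

```
label	MFX001	MFX002	MFX003	MFX004	MFX005
T90001	0.0	0.0	0.5	0.6	0.5
T90002	0.0	0.75	1.0	0.2	1.0
T90003	1.0	0.75	0.5	0.6	0.5
```

Each cell is the completeness of one module in one genome (T90003 has
module MFX001 complete, T90001 lacks it entirely). The automated report
(`modq report --mcf out/mcf.tsv --factor fx/factors.tsv --out rep`)
turns such a matrix into a heatmap, per-module boxplots, an SD scatter,
a zero-variance table, group-mean heatmaps, principal-component plots and
per-group spread statistics, plus `summary.json` and `report.md`.

Other subcommands: `module-to-genomes` (genomes complete above a
threshold, default 1), `gene-to-modules`, `genes-to-genomes`,
`missing-genes`, `translate-defs`.

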