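# ggclone

**In silico Golden Gate assembly for multi-gene pathway engineering in
*Yarrowia lipolytica*.**

`ggclone` is a designer/simulator for a BsaI-based modular cloning
toolkit in which typed building blocks — selection markers, promoters,
coding genes, terminators — carry predesigned 4-bp fusion sites
(numbered 1–11) and are assembled in one pot into destination backbones
pGGYL1, pGGYL2 and pGGYL3, which accept 4, 7 and 10 fragments (one
marker plus 1–3 transcription units).  The assembled plasmid is
linearized with SwaI to release an integration cassette for
NHEJ-mediated random chromosomal integration.  The package is aimed at
strain engineers who want to validate parts, predict assembly outcomes
and mis-joins, plan combinatorial promoter/terminator libraries and
multi-round pathway builds, and keep the strain-improvement arithmetic
honest — before touching a pipette.

## The model

A type IIS enzyme cuts outside its recognition sequence: for BsaI
(GGTCTC, N1 spacer, 4-nt 5′ overhang) a plus-strand site at recognition
start *p* cuts the top strand at *p* + 7 and the bottom at *p* + 11,
leaving the 4-mer between the cuts as a programmable sticky end.  Sticky
ends are normalized to their top-strand reading, so two ends ligate
exactly when their normalized 4-mers are equal.  One-pot assembly is
modelled as the set of circular closures over the digested fragment
pool; because correct products lose every recognition site while any
circle that retains one is re-cut by the cyclic digestion–ligation
program, the *stable* products are the site-free closures.  Under a
faithful fusion-site table (no duplicates, no reverse-complement pairs,
no palindromes) the intended plasmid is the unique stable closure
containing the backbone; planted collisions are detected and reported
as mis-join ambiguity.  Colonies are called blue when the lacZ stuffer
survives and white otherwise — including mis-joined white false
positives, which is why the simulator also reports junction order and
verification-PCR amplicon lengths.

Because the physical toolkit's sequences are not distributed with the
package, it ships a seeded generator that builds a fully
synthetic but structurally faithful toolkit (8 promoters, 9
terminators, the 8 mevalonate-pathway genes plus a bisabolol-synthase
stand-in, 6 markers, 3 backbones), every sequence a pure function of
the seed.

## Worked example

```python
import ggclone as gg
from ggclone.fixtures import FixtureConfig, gen_demo_toolkit

registry = gen_demo_toolkit(FixtureConfig(seed=11))
design = gg.AssemblyDesign("pGGYL1", ["HUH", "P_GPD", "MrBBS", "T_Mig1"])
product, side_products = gg.simulate_assembly(design, registry)
print(product.colony_color, product.junctions)
```

prints

```
white [(1, 'AAAC'), (2, 'AACA'), (3, 'AAGG'), (4, 'ACAA'), (5, 'ACCC')]
```

— a white colony whose five junctions run in slot order, i.e. the
unique stable closure is the intended 4,517-bp plasmid; the 26 side
products are the blue backbone religation, donor religations and
re-cuttable chimeras.  Extracting the cassette and running the
verification PCR:

```python
cassette, vector = gg.extract_cassette(product.sequence)
amp = gg.in_silico_pcr(product.sequence)
```

yields a cassette carrying the marker and one transcription unit (kanR
and ori stay on the 1,332-bp vector fragment) and an amplicon exactly
as much longer than the empty-backbone amplicon as the parts swapped in
for the stuffer.  The scripts in `examples/` walk through every
capability (assembly, domestication, cassette + PCR, marker recycling,
round planning and metrics) and print the numbers they compute.

The same operations are exposed on the command line:

```bash
ggclone gen-fixtures --seed 11 --out registry.json
ggclone assemble --design design.yaml --registry registry.json --out product.gb
ggclone ladder --ledger titers.tsv
```

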