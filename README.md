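# concatag

Concatemer-tag gene expression profiling, in silico: design multiplex
chimeric-primer panels, simulate the amplification → restriction digestion →
concatemer ligation → cloning → sequencing protocol from a ground-truth
expression profile, deconvolve clone reads back into per-gene tag counts, and
estimate control-normalized relative expression with a comparative-CT
(ΔΔCT) cross-check.

## How it works

1. **Panel design** (`concatag.panel_design`). Each primer is chimeric: a
   16–20 nt gene-specific 3′ part fused to a universal adaptor tag (18 nt
   with one BamHI site, 19 nt with one HindIII site). Candidate pairs are
   enumerated exhaustively under the constraints (PCR product 85±7 bp,
   digested tag 60–70 bp, no internal restriction sites) and one pair per
   gene is selected to minimize the panel's melting-temperature spread
   (nearest-neighbor Tm, SantaLucia 2004 table, Owczarzy Mg²⁺ correction),
   enforcing a pairwise ΔTm ≤ 5 °C. Selection is exact and deterministic.
2. **Protocol simulation** (`concatag.wetlab_sim`). Molecules are drawn
   multinomially from the expression profile, digested into canonical tags
   (BamHI hexamer first, overhangs filled), ligated into sticky-end
   concatemers whose orientations strictly alternate, size-selected to
   500–1200 bp, and 300 clones are sequenced with an optional substitution
   error model. Every clone carries its ground truth.
3. **Deconvolution** (`concatag.deconvolution`). Reads are split at junction
   hexamers (shared-boundary convention, identical to the simulator's),
   orientations inferred, and each fragment assigned to a gene by
   mismatch-tolerant Hamming comparison against the expected tags in both
   orientations (default max 2 mismatches, margin ≥ 2 to the runner-up).
4. **Quantification** (`concatag.quantify`). Ratios of control-normalized
   counts between conditions, with Katz-log 95% confidence intervals and
   up/down/unchanged calls; ΔCT/ΔΔCT analysis of qPCR CT tables (ΔCT =
   CT(control) − CT(target)), standard-curve amplification efficiency, and a
   per-gene concordance table between the two methods.

Synthetic fixtures (20-gene sets with an ACT1 internal control,
two-condition profiles spanning ≥16-fold, matched qPCR CT tables) are
generated deterministically by `concatag.datasets`.

## CLI

```sh
concatag design     --genes genes.fasta --control ACT1 --out panel
concatag simulate   --panel panel.panel.tsv --genes genes.fasta \
                    --profiles profiles.tsv --seed 1 --out sim/
concatag deconvolve --reads treated=sim/reads_treated.fasta,untreated=sim/reads_untreated.fasta \
                    --panel panel.panel.tsv --genes genes.fasta --out counts/
concatag quantify   --counts counts/counts.tsv --treated treated \
                    --untreated untreated --control ACT1 --out estimates.tsv
concatag compare    --estimates estimates.tsv --qpcr qpcr_ct.tsv \
                    --treated treated --untreated untreated --control ACT1 \
                    --out concordance.tsv
concatag run-all    --seed 1 --out run/          # whole pipeline on the packaged fixture
```

All tables are TSV; sequences are FASTA; configuration is YAML (see
`concatag.cli_io.RunConfig` for every key). Exit codes: 0 ok, 2 user error,
3 data error.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests,
brute-force oracle equivalence checks (candidate enumeration, panel
selection, tag assignment, junction finding) and `tests/test_acceptance.py`,
which asserts the protocol-level acceptance criteria (tags/clone, insert
size window, panel constraints, 20-plex detection, lossless round trip,
parameter recovery, closed forms).

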