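# introscan

Coverage-based detection of large inter-specific introgressions in crop
genomes from low-pass sequencing data.

Genebanks and breeding programs hold thousands of wheat accessions whose
alien chromatin — rye 1RS translocations, whole-chromosome substitutions
from *Thinopyrum* and other wild relatives — is largely undocumented.
These segments leave a strong mapping signature even in data far too
shallow for variant calling: reads from an introgressed segment fail to
map to the corresponding interval of the host reference (a coverage
deficit), and in substitutions they pile onto the most similar remaining
homoeologue (an excess). `introscan` turns that signature into calls from
genotyping-by-sequencing (GBS) or ultra-low-coverage WGS alignments, for
curators and breeders screening whole collections.

## Method

For every 1-Mb window (configurable) the *breadth of coverage* — the
fraction of positions covered by ≥ 1 read after `samtools`-style FLAG
filtering (`-F 2308`) — is computed, giving a per-sample profile `v`.
Calling proceeds in four steps:

1. **Initial calling.** WGS: window `i` is seeded when
   `|v_i − median(v)| > 1.5 · MAD(v)`, labeled LOW or HIGH by the sign of
   the deviation. GBS: sample and a reference-genotype GBS profile are
   median-normalised and the relative deviation `(s_i − r_i)/r_i` is
   thresholded at 20% (the normalisation cancels the restriction-enzyme
   capture pattern shared by all GBS libraries).
2. **Denoising.** Same-label runs shorter than 5 windows are erased.
3. **Gap filling.** A gap between two same-label runs is filled iff every
   gap window's step-1 deviation already has the matching sign.
4. **Pruning.** Runs shorter than 25 windows are erased — only
   introgressions ≥ 25 Mb (at 1-Mb windows) are reported.

Around the caller: donor inference against a concatenated host+donor
reference (which donor chromosome attracts the missing reads), per-window
Fisher exact tests for introgression enrichment between sample groups,
missing-subgenome flagging, pairwise screening of call tracks for
heterogeneous or duplicated accessions, a two-tier simulator
(profile-level and read-level with SAM output), and dot-plot
visualisation. See `docs/methods.md` for the full model and its
assumptions.

## Worked example

Simulate a 1-Mb-scale toy accession carrying a 400-kb introgression from a
distant donor (similarity 0.3, i.e. the segment retains 30% of baseline
breadth) and call it:

```sh
cat > sim.yaml <<'YAML'
chromosomes:
  - {name: 1A, length: 1000000, subgenome: A}
  - {name: 1B, length: 1000000, subgenome: B}
window_size: 10000
baseline: 0.10
noise_sd: 0.01
seed: 11
sample: acc1
segments:
  - {chromosome: 1B, start_window: 30, n_windows: 40, similarity: 0.3}
YAML
introscan run --config sim.yaml --out out
```

prints

```
1 calls covering 40 windows -> out
```

and `out/calls.bed` contains exactly the implanted interval —
windows 30–69 of 1B, labeled as a coverage deficit for sample `acc1`,
40 windows wide:

```
#chrom	start	end	name	score	strand
1B	300000	700000	acc1|LOW	40	.
```

`out/` also holds the per-window track (`track.tsv`: breadth, raw
deviation and final label per window, the release format for calls at
window resolution), the truth intervals, a dot plot (`plot.png`; black =
expected breadth, red = deficit, blue = excess), and a JSON provenance
record of parameters and input checksums. The same library surface is
available programmatically (`introscan.call_introgressions`,
`introscan.simulate_profile`, …), and `introscan --help` lists the other
subcommands (`coverage`, `call`, `donor`, `enrich`, `compare`, `plot`,
`simulate`).

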