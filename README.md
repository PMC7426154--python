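# hbramp

Position-dependent hydrogen-bond analysis of ORFeomes: per-codon
hydrogen-bond profiling, positional codon-usage metrics, bounded-exponential
ramp fitting, and a synonymous-codon-shuffling selection test.

## The scientific problem

In double-stranded DNA every A·T base pair holds two hydrogen bonds and
every G·C pair three, so a codon carries between 6 (e.g. `TTA`) and 9
(e.g. `GCG`) bonds, and synonymous codon choice can change that count by up
to 25% (leucine: `TTA` = 6 vs. `CTG` = 8 bonds).  Because transcription must
melt these bonds to expose the template strand, position-dependent codon
usage bias can create a position-dependent *energetic* cost of unwinding a
gene.  In many bacterial and archaeal ORFeomes (the complete CDS
complements of genomes) the mean bond count per codon rises from the 5′ end
of CDSs and saturates within ~15–20 codons — a "ramp" of hydrogen bonding.

`hbramp` is a toolkit for detecting, modelling and stress-testing that
signal in any CDS collection:

- **Profiling** (`orfeome`, `profiles`, `metrics`): QC of CDSs, a
  left-aligned codon matrix (start codon removed; column labels are
  original codon positions 2, 3, …), and per-position means with 95%
  nonparametric bootstrap CIs (1,000 resamples of whole CDSs) for hydrogen
  bonds, cheap (6–7 bond) / expensive (8–9 bond) codon frequencies, RSCU,
  CAI, tAI, and mRNA unpaired-probability profiles parsed from an external
  RNA-folding tool's output.

- **Ramp model** (`ramp`): weighted least-squares fits of

  $$y(x) = \frac{A\,C\,e^{Bx}}{A + C\,(e^{Bx}-1)}$$

  — carrying capacity $A$ (bonds/codon plateau), rate $B$ (per codon
  position), initial content $C = y(0)$ at the first codon after the start
  — against uniform ($y=A$) and linear ($y=Bx+C$) alternatives, with
  AIC/BIC model selection, Wald tests, and the min/trimmed-mean fallback
  parameters for profiles the exponential cannot fit.

- **Selection test** (`selection`): a null model built from 200 ORFeomes
  whose synonymous codons are shuffled within each CDS (amino-acid
  sequence and per-CDS codon composition preserved), yielding per-position
  $z^2 = ((O-E)/\sigma)^2$ (a $\chi^2$ decomposition) and the signed
  χ-gram $(O-E)/E$; a negative 5′ χ-gram means selection toward *fewer*
  hydrogen bonds at the 5′ end.

- **Strata analysis** (`strata`): comparisons by position of a CDS within
  its operon and by expression stratum (top/bottom percentile in every
  experiment of an RNA-seq compendium), with Wilcoxon / Kruskal–Wallis
  tests and Benjamini–Yekutieli correction, plus Spearman correlation
  networks among positional metrics.

- **Synthetic data** (`simulate`): generator of ORFeomes whose positional
  mean bond count follows a chosen ramp exactly (exponential tilting of
  synonym choice, solved per position), with operon tables and expression
  compendia carrying implanted ground-truth effects — every pipeline stage
  is testable without downloads.

## Worked example

Generate a 2,000-CDS synthetic ORFeome with an implanted ramp
($A{=}7.9$, $B{=}0.3$, $C{=}7.0$), profile it, fit the models, and run the
selection test:

```sh
hbramp simulate --n-cds 2000 --length 101 --ramp 7.9,0.3,7.0 --seed 1 --out-dir sim
hbramp profile sim/orfeome.fasta --seed 1 --out-dir profiles
hbramp fit profiles/hbond_profile.tsv --seed 1 --out ramp_fit.json
hbramp selection sim/orfeome.fasta --n-sims 200 --seed 1 --out-dir sel
```

`profiles/hbond_profile.tsv` starts at the first codon after the start
codon (position 2, mean 6.99 bonds — the initial content $C$) and rises
position by position (7.20 at position 3, …):

```
position  mean    ci_low     ci_high    se          n     metric
2         6.9945  6.9644875  7.0295125  0.01812...  2000  hbond
3         7.2     7.1634875  7.235      0.01818...  2000  hbond
```

`ramp_fit.json` names the bounded exponential as the selected model and
recovers the implanted parameters:

```
selected: bounded_exponential
params:   A = 7.9009   B = 0.3122   C = 6.9883
se:       A = 0.0016   B = 0.0081   C = 0.0141
p(B) = 7.8e-61,  AIC = -5.0 (uniform 405.5, linear 391.1),  success: true
```

$A$, $B$ and $C$ land within ~0.1%, 4% and 0.2% of the truth; the rate is
overwhelmingly significant, so the `success` flag (best under both AIC and
BIC with $p(B) < 0.001$) is set.  `sel/selection_summary.json` shows the
direction of the implanted signal against the shuffling null:

```
head_mean_chigram = -0.0211   (positions 2-16: fewer bonds than expected)
tail_mean_chigram = +0.0037
head_mean_normalized_z_sq = 0.196 vs. tail 0.0096  (selection concentrated 5')
```

The 5′ χ-gram is negative — the observed ORFeome uses codons with fewer
hydrogen bonds at the 5′ end than its own synonymous shuffles — and the
normalized $z^2$ profile peaks in the first 15 positions, exactly the
implanted ramp.  A flat control (`--ramp flat`) selects the uniform model
and shows no 5′ signal.

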