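# lhekit

Characterization toolkit for engineered LAGLIDADG homing endonucleases
(LHEs) and megaTAL fusions.

LHEs are compact enzymes whose ~20 bp recognition sites make them
attractive scaffolds for therapeutic genome editing — for example,
re-targeting the I-AniI enzyme to the XID point-mutant allele of the mouse
*Btk* gene, a model of human X-linked agammaglobulinemia. Evaluating such
an enzyme is a computational pipeline as much as a wet-lab one, and that
pipeline is what this package implements:

* **Target-site model** (`lhekit.sites`) — signed ±position coordinates
  around the cleavage point, mismatch-label nomenclature (`-10G-8A`),
  composite reporter sites, and 52 bp dsOligo substrate construction.
* **Specificity profiling** (`lhekit.specificity`) — enumeration of all 3L
  one-off variants, normalization of cleavage to the on-target value
  (r = 1), classification of positions as *specific* vs *degenerate* at a
  threshold θ (r > 0.5 of on-target), and the **tolerance-combination
  rule**: a multi-mismatch site is predicted cleavable iff every
  constituent single mismatch is individually tolerated.
* **Off-target scanning** (`lhekit.offtarget`) — exhaustive both-strand
  k-mismatch search over FASTA genomes, with mismatch labels and
  profile-based tolerance calls per hit; BED6/TSV output.
* **Disruption readout** (`lhekit.readout`) — global affine alignment of
  amplicon reads, left-aligned indel calls, intact/NHEJ/HDR/fail
  classification against a cut window (default: the central four bases of
  the site), disruption/HDR rates with Wilson 95% CIs, and fold changes
  between loci.
* **Assay quantification** (`lhekit.assays`) — yeast-surface cleavage
  index (1 − median Mg²⁺/median Ca²⁺), traffic-light-reporter NHEJ/HDR
  fractions within an expression gate, gel cleavage fraction, and
  saturation-binding fits of F(c) = F0 + Fmax·c/(Kd + c) by
  Levenberg–Marquardt with multi-start.
* **Synthetic data** (`lhekit.simulate`) — seeded generators for genomes
  with planted near-match sites, profiles with designated tolerated cells,
  reads with planted indels and sequencing error, titrations, and flow
  event tables — each with a serialized ground-truth record.
* **Pipeline & CLI** (`lhekit.pipeline`, `lhekit.cli`) — a JSON-configured
  end-to-end run (profile → scan → predict → disrupt) and a thin `lhekit`
  command with `scan`, `profile`, `disrupt`, `fit-kd`, `tlr`,
  `cleave-index`, `simulate`, and `run` subcommands.

See `docs/methods.md` for the models and numerical choices, and
`examples/` for one narrative script per capability.

## Worked example

```python
import lhekit as lk

# the native and re-targeted sites differ at nine labelled positions
m = lk.mismatches(lk.ANI_SITE, lk.XID_SITE)
print(len(m), m.label)
# 9 -10A-8T-6C-5C-4T+6T+7G+9C+10T
```

Scanning a synthetic genome with planted near-match sites and triaging the
hits with a specificity profile (`examples/03_offtarget_scan.py`):

```text
scanned 100000 bp, 4 hits:
  chr1:8447-8467 (+) 2 mm [   -10G-8A] -> tolerated
  chr1:51270-51290 (-) 2 mm [    +4T+8G] -> not_tolerated
  chr1:62061-62081 (+) 1 mm [       -5T] -> tolerated
  chr1:92590-92610 (+) 0 mm [     exact] -> tolerated
```

Each hit is a genomic window within 2 mismatches of the XID site on either
strand; the prediction column applies the combination rule — `-10G-8A` is
tolerated because both of its single mismatches exceed 50% of on-target
cleavage in the profile, while `+4T+8G` fails on at least one.

Disruption rates from cloned-amplicon reads
(`examples/04_amplicon_disruption.py`):

```text
reporter + exonuclease (27/28): 96.4% disrupted (95% CI 82.3-99.4%)
endogenous site in MEFs (21/53): 39.6% disrupted (95% CI 27.6-53.1%)
2-mismatch off-target (3/41): 7.3% disrupted (95% CI 2.5-19.4%)
on-site vs off-site fold change: 5.4x
```

A read counts as disrupted (NHEJ) when an indel touches the central four
bases of the recognition site; the fold change compares on-target editing
to residual off-target editing.

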