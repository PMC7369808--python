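# Methods

## Scope and model

`repairguide` treats site-directed A-to-I editing as a pure sequence
transformation: inosine is read as guanosine by the ribosome and by
sequencing polymerases, so an edit is an in-place A→G substitution and every
downstream prediction (translation, bystander consequences, simulated
chromatograms) follows from the standard genetic code. No editing-efficiency,
RNA-structure or deaminase-preference model is included: efficiency enters
only at the population level, as the edited fraction *f* of a sequenced
amplicon pool.

Inputs are cDNA/mRNA sequences (FASTA; DNA or RNA alphabet, normalised to
DNA) with a 1-based `orf_start` annotation. All interfaces speak 1-based,
inclusive coordinates; `c.1` is `orf_start`. IUPAC ambiguity codes are
rejected outright — designing a spacer against an ambiguous base would be
silently wrong.

### Terminal-stop convention

Transcripts carry no ORF-end annotation, so the terminal stop is defined as
the **last** in-frame stop codon of the record; every in-frame stop upstream
of it is a PTC, and "full-length" translation means reaching it. This is
exact for ORF-spanning cDNAs (the intended inputs). For transcripts whose 3′
UTR contains in-frame stops the convention misplaces the ORF end — trim such
inputs to the ORF. A record whose only stop is followed by further sense
codons is read as stop + 3′ UTR.

### Stop-codon rescue

A→G substitution within a stop codon can only produce TGG (Trp): opal TGA
needs its 3rd base edited, amber TAG its 2nd, ochre TAA both — which is why
ochre sites are flagged `requires_two_edits` and refused by the outcome
predictor unless explicitly overridden (simultaneous double deamination at
one codon is outside single-site editing scope). The `g.<pos>G>A` notation
names the presumed G>A event that created the stop and is emitted only for
single-edit sites.

## Spacer geometry

The mismatch distance *d* counts from the spacer 3′ end (3′-terminal base =
position 1); because the dCas13b scaffold is cloned immediately 3′ of the
spacer, *d* also equals the distance between the target adenosine and the
first scaffold nucleotide. The spacer 3′ end pairs with the lowest transcript
coordinate of its window, giving window = `[a − d + 1, a + L − d]`. Both
facts are enforced by an independent base-by-base antiparallel pairing oracle
in the test suite rather than assumed. An off-by-one in either convention
would silently shift the edited base, which is why they are stated here and
tested against 500 random geometries.

The 5′-G requirement (efficient U6 transcription) defaults to `substitute`
— overwrite the 5′ base, preserving the printed lengths L and the distance
d; `prepend` (L+1) and `require` are available. When *d = L* the mismatch C
itself sits at the 5′ end and `substitute` would destroy it; this raises an
error directing the user to `prepend`. Whether a guide's 5′ base is natural
or substituted is recorded in `five_prime_base_modified`.

Cloning overhangs default to `CACC`/`CAAC` with BbsI. These are conventional
golden-gate choices, explicitly provisional and configurable; the guaranteed
property — tested — is the duplex invariant: stripping the overhangs and
annealing reconstructs the spacer exactly.

Designs are reported in grid order; no ranking score is invented, since guide
performance differences are an empirical matter the sequence alone does not
predict.

## Bystander assessment

Every adenosine in the spacer window is annotated with the consequence of
editing it *alone* (synonymous, missense, stop-lost, stop-introducing,
outside-ORF, or the intended repair at the target). Combinatorial multi-site
editing is not modeled, and no per-site editing probability is assigned —
without a validated deaminase-preference model, enumeration without weights
is the honest computable core. Note that under the standard code a single
A→G edit can never *create* a stop codon (the class is retained for
completeness and is provably empty).

## Sanger trace simulation

Traces are modeled at base-call resolution: one four-channel (A,C,G,T)
peak-height vector per template base, in units of the mean called-peak
height. Scan-point Gaussians, mobility correction and base-calling are out
of scope — minor-peak visibility only needs called heights.

- Non-site position: called channel ~ Normal(1, `peak_height_cv`); each
  other channel ~ Uniform(0, `noise_floor`) + `crosstalk` × called height.
- Edited site (template A, edited fraction *f*): channel A gets
  (1−f)·Normal(1, cv), channel G gets f·Normal(1, cv) (independent draws),
  each plus its own baseline; C and T behave as non-called channels.

Quantification mirrors how an analyst reads a chromatogram. Baseline noise
(mean μ, SD σ) is estimated from the non-called channels of 10 flanking
positions per side (shrunk with a warning near trace ends; < 3 per side is
an error). A secondary peak is *called* when the smaller of the A/G heights
reaches μ + kσ (k = 3). The edited fraction is estimated as
f̂ = G/(A+G) after subtracting μ from each channel and clipping at zero;
clipping avoids negative fractions at low f.

### Parameter defaults and calibration

| parameter        | default | meaning                                    |
|------------------|---------|--------------------------------------------|
| `peak_height_cv` | 0.10    | relative SD of a called peak height        |
| `noise_floor`    | 0.21    | baseline upper bound, fraction of peak     |
| `crosstalk`      | 0.01    | spectral bleed-through between channels    |
| `detection_k`    | 3.0     | σ-multiple for the secondary-peak call     |

The detection rule (3σ, and "detectable" = called in ≥ 90 % of replicates)
is a modeling choice; given that rule, `noise_floor` and `crosstalk` were
calibrated so that the smallest detectable fraction on a 0.05-step grid is
0.30 — the sensitivity limit of standard dye-terminator sequencing of mixed
amplicons, at which a 1:1 or 2:1 wild-type:mutant mix shows a clear double
peak while bulk editing below ~30 % stays invisible. Under these defaults
the 1:1 (f = 0.5) and 2:1 (f = 1/3) mixes are detected in ≥ 98 % of
replicates, f = 0.05 in < 1 %, and the estimator bias is ≤ 0.02 for
f ∈ [0.1, 0.9] (≈ −c(1−2f) from crosstalk inflating the baseline estimate,
plus a small clipping term at the extremes). Every parameter is overridable
per run.

Determinism: `TraceModel.seed` drives all draws; the detection-limit sweep
spawns an independent child seed per grid fraction, so each fraction's rate
is reproducible regardless of which other fractions are run.

Problem sizes: the detection-limit experiment uses a 60-nt template with the
editable site centered, a 0.05–0.50 grid in 0.05 steps, and 100 replicates
per fraction — ample for a rate threshold at 0.90 while keeping the whole
sweep to a few seconds.

Only TSV trace tables (`position, A, C, G, T`) are read; AB1 chromatograms
raise an explicit "format not enabled" error rather than a silent fallback.

## Synthetic fixtures

The fixture generator emulates the two reference systems — a 400-codon
reporter ORF with opal W190X (editable A at position 570 = 3 × 190) and a
1500-codon CFTR-like ORF with opal W1282X (g.3846G>A) — as random sense
codons around a planted stop: ATG first, terminal TAA last, no other
internal stop, BbsI-site-free by resampling, deterministic under a seed.
Every coordinate-level claim (570, 3846, grid counts, restored residue
indices) is arithmetic in the codon index and therefore independent of the
particular random codons; what the synthetic ORFs do **not** emulate is real
codon usage, UTRs, splicing or RNA secondary structure, so passing tests
validate coordinate and design logic, not in-cell editability of any real
transcript. Real cDNAs can be supplied as FASTA at any entry point.

## Known limitations

- The terminal-stop convention above for transcripts with in-frame UTR stops.
- No gRNA folding or accessibility scoring; no editing-efficiency model.
- Bystander enumeration is single-site and unweighted.
- The trace model is a calibrated abstraction of one instrument class; the
  ~30 % limit is instrument- and basecaller-dependent in practice.
- Transcriptome-wide off-target search is out of scope.
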