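# repairguide

Design and quality control of dCas13b/ADAR guide RNAs for repairing premature
termination codons (PTCs) by site-directed A-to-I RNA editing.

Nonsense mutations place a premature stop codon (UGA/UAG/UAA) in an mRNA and
truncate the protein — in cystic fibrosis, for example, the *CFTR* W1282X
allele. RNA-editing platforms that tether the deaminase domain of human ADAR2
to catalytically dead PspCas13b can convert the stop codon's adenosine to
inosine, which ribosomes and sequencing polymerases read as guanosine: an opal
UGA becomes UGG (Trp), restoring full-length protein without touching the
genome. The editing site is selected by a guide RNA whose *spacer* is
antisense to the mRNA around the target adenosine, with a deliberate C:A
mismatch placed opposite it.

`repairguide` is the desk-side toolkit for that workflow. It

- **scans** an ORF for premature stop codons, classifies them
  (opal/amber/ochre), and reports each editable adenosine in transcript,
  CDS (`c.`) and record (`g.`) coordinates;
- **designs** spacers with explicit geometry — length *L* (guides of
  25–80 nt), mismatch distance *d* (position of the mispaired C counted from
  the spacer 3′ end, which abuts the dCas13b scaffold), a 5′-G policy for U6
  transcription — and emits annealing-ready oligo pairs with directional
  BbsI golden-gate overhangs;
- **assesses bystanders**: every other adenosine in the spacer window,
  annotated with the protein consequence of its collateral editing;
- **predicts outcomes**: applies the A→G edit plan, re-translates, and
  reports whether the stop is removed and translation runs full length;
- **simulates Sanger electropherograms** of partially edited amplicon
  populations and quantifies the minor G peak, modeling the detection limit
  of bulk editing by standard sequencing (~30 % edited transcript under the
  default noise model).

## Spacer geometry

For a target adenosine at transcript position *a*, a spacer of length *L*
with mismatch distance *d* hybridises to the window
`[a − d + 1, a + L − d]` (1-based, inclusive). The spacer is the reverse
complement of that window with the base opposite *a* replaced by C; its 3′
end pairs with the lowest window coordinate, so the mispaired C lies exactly
*d* nt from the 3′ end — equivalently, *d* nt from the first scaffold
nucleotide. The reference geometries are the four reporter guides
(50–32, 50–34, 50–35, 30–25) and the three CFTR guides (50–32, 50–34, 50–35).

## Worked example

Generate the synthetic CFTR-like transcript (1500 codons, opal stop at codon
1282), scan it, and design the 50–34 guide:

```sh
$ repairguide fixtures --preset cftr-w1282x -o cftr.fasta
cftr_w1282x (4500 nt) written to cftr.fasta

$ repairguide scan cftr.fasta
record_id    codon_index  stop_class  codon  adenosine_positions  edit_plan  g_notation  c_notation  restored_residue  requires_two_edits
cftr_w1282x  1282         opal        TGA    3846                 3846       g.3846G>A   c.3846G>A   W                 False

$ repairguide design cftr.fasta --target-a 3846 --length 50 --distance 34 -o w1282x_50-34
1 design(s) written to w1282x_50-34.json and w1282x_50-34.spacers.fasta

$ cat w1282x_50-34.spacers.fasta
>cftr_w1282x_A3846_50-34
GTAAGATGACCCCGGGCCATATCGACGTCTCAGGCGGTCCTTCTAAGGGG
```

The scanner reads the opal TGA at codon 1282, whose editable adenosine is the
third codon base at transcript position 3 × 1282 = 3846 (`g.3846G>A` names
the presumed G>A substitution that created the stop). The 50-nt spacer
carries the mismatch C 34 nt from its 3′ end (position 17 counting from the
5′ end), sitting opposite the target adenosine. Cloning oligos and the repair
prediction:

```sh
$ repairguide oligos w1282x_50-34.json
name                     top_oligo                                               bottom_oligo                               enzyme
cftr_w1282x_A3846_50-34  CACCGTAAGATGACCCCGGGCCATATCGACGTCTCAGGCGGTCCTTCTAAGGGG  CAACCCCCTTAGAAGGACCGCCTGAGACGTCGATATGGCCC...  BbsI

$ repairguide outcome cftr.fasta --codon 1282
{ "restored_residue_index": 1282, "restored_residue": "W",
  "premature_stop_removed": true, "full_length": true, ... }
```

Editing position 3846 turns TGA into TGG: tryptophan 1282 is restored and
translation runs to the terminal stop. Finally, the sequencing detection
limit under the default trace model:

```sh
$ repairguide detection-limit --grid 0.1:0.5:0.1 --reps 50 --seed 42
fraction  detection_rate
0.10      0.12
0.20      0.48
0.30      0.92
0.40      1.00
0.50      1.00
detection_limit  0.30
```

Below ~30 % edited transcript the minor G peak does not reliably clear the
3-σ baseline-noise threshold — editing can be real yet invisible to standard
Sanger sequencing of the bulk cDNA.

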