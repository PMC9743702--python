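# ratchetscan

Tools for modelling how the eukaryotic ribosomal preinitiation complex
(PIC) finds a start codon when scanning is a **Brownian ratchet** rather
than a strictly one-way walk, and for the data analyses that test this
model: quantification of reporter libraries sorted by fluorescence
(FACS-seq), parameter fitting against those measurements, and genome-wide
scans for the evolutionary footprint the model predicts.

## Who this is for

Researchers studying translation initiation — leaky scanning, start-codon
context (Kozak) strength, competition between closely spaced AUGs, and
nonsense-mediated decay (NMD) triggered by out-of-frame initiation — who
want a tested, reproducible implementation of:

1. **A ratchet-and-pawl random walk simulator** (`ratchetscan.ratchet_core`).
   The PIC moves 1 nt per step, 5'→3' or 3'→5' with equal probability.  A
   "pawl" (a 5' block) is deposited immediately behind the PIC with
   probability *p.Pawl* per step; the cap and the pawls forbid backward
   moves, rectifying the oscillation into net forward progress.  The
   P-site sits at the 13th–15th nt of the PIC footprint; each time an AUG
   occupies it, recognition fails with probability *p.Leakage* (per-site
   overrides model context strength).  Initiation at an out-of-frame AUG,
   or runoff past the 3' end of the window, triggers mRNA decay with
   probability *p.NMD*.  An exact absorbing-Markov-chain solver over
   (trailing edge, pawl frontier) states provides the same quantities
   without Monte-Carlo noise and validates the simulator.

2. **Parameter inference** (`ratchetscan.inference`).  A coarse grid
   screen over (*p.Pawl*, *p.Leakage*, *p.NMD*) followed by greedy
   sequential-update chains: one parameter proposed at a time from a
   uniform window centred on the current value, accepted only when the
   residual sum of squares (RSS) against Solo-normalised GFP intensities
   decreases.  Per-context leakage is fitted with the other two
   parameters pinned.  Derived quantities include the *net* leakage rate
   (the fraction of PICs that never initiate at the annotated start after
   all inspections) and the implied number of scans per triplet,
   `log(net) / log(single-scan leakage)`.

3. **FACS-seq quantification** (`ratchetscan.library_quant`).  Pattern
   matching of paired amplicon reads (fixed flanks, four 6-nt barcodes,
   a doped variable region), the three read-rejection rules, variant
   annotation (ATG positions/frames/−3 contexts, stop codons, upstream
   ATGs), the ordered variant filters, and the bin-weighted intensity
   `GFP_j = Σ G_i·n_ij·P_i / Σ n_ij·P_i` plus RNA/DNA read-fraction
   ratios for mRNA levels.

4. **Genome scans** (`ratchetscan.genome_scan`).  Per-position counts of
   genes harbouring a downstream ATG (dATG) in the 45 nt after the
   annotated start, stratified by frame and −3 context, Spearman trend
   tests, expression-stratified comparisons, and codon adaptation index
   (CAI) of the early coding region.

5. **Synthetic data with ground truth** (`ratchetscan.synthetic_data`).
   Doped-oligo libraries, model-generated observation tables, complete
   FACS-seq read sets, and CDS collections with planted positional dATG
   bias — everything needed to test the pipeline end to end.

## Worked example

```python
import numpy as np
import ratchetscan as rs

params = rs.ScanParameters(p_pawl=0.001, p_leakage=0.77, p_nmd=0.62)
solo = rs.solo_layout()                    # 50 nt UTR, aATG, 50 nt window
duo = rs.duo_layout(9)                     # extra out-of-frame ATG at +9

rng = np.random.default_rng(42)
s = rs.simulate_ensemble(solo, params, 10_000, rng)
d = rs.simulate_ensemble(duo, params, 10_000, rng)

print(f"net leakage          {s.net_leakage:.4f}")
print(f"scans per triplet    {rs.scans_per_triplet(0.08, 0.77):.2f}")
print(f"Duo(+9) expression   {rs.expression_level(d, s):.3f}")
```

prints

```
net leakage          0.0694
scans per triplet    9.66
Duo(+9) expression   0.861
```

Under the fitted probabilities, about 7% of PICs never initiate at a lone
annotated start even after ~10 inspections per triplet, and an
out-of-frame ATG at +9 pulls normalised reporter expression down to ~0.86
— both through direct competition for initiation and through NMD of
transcripts whose PICs initiated out of frame.  The exact solver gives
the same numbers without sampling noise:

```python
rs.exact_recognition_probabilities(duo, params).expression
```

A command-line interface mirrors the library:
`ratchetscan simulate|fit|quantify|genome-scan|synthesize --help`.

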