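# pals

Peptide-barcode design and relative quantitation for **pooled lipid
nanoparticle (LNP) screening by mass spectrometry**.

Screening mRNA-delivery LNPs one formulation per animal group is slow and
animal-hungry. If each LNP instead carries an mRNA encoding the same
carrier protein with a *unique C-terminal peptide barcode*, many LNPs can
be dosed together: tryptic digestion of the expressed protein releases one
reporter peptide per LNP, and the extracted-ion peak area of each barcode
measures how much protein that LNP delivered. `pals` implements the
computational core of this workflow:

- **`pals.chem`** — monoisotopic peptide masses, precursor m/z, and the
  singly-protonated b/y fragment series (with the proline diagnostic y-ion).
- **`pals.design`** — the barcode design cascade: enumerate 5-residue cores
  over an 11-letter alphabet (M, W, N, Q, C, R, K, D, E excluded), keep
  cores with exactly one proline, assemble them between constant 6-residue
  flanks, and select panels resolvable at MS1 (unique precursor mass) or
  MS2 (distinct fragment ions among isobaric groups).
- **`pals.digestion`** — in-silico trypsin digestion (cleave after K/R, not
  before P) and verification that a barcoded construct releases exactly the
  designed barcode peptides.
- **`pals.mrna`** — reverse translation into an ORF hitting a target GC
  fraction (default 62%) and assembly of the `5'UTR + ORF + 3'UTR +
  poly(A)120` mRNA layout.
- **`pals.quant`** — per-animal normalization of peak areas to a reference
  barcode, LNP ranking by mean fold change, exact small-n Wilcoxon
  matched-pairs signed-rank tests, method-agreement r², and LOQ censoring.
- **`pals.sim`** — a pooled-screen simulator (Hill/Emax dose–response per
  LNP, shared per-animal lognormal factors, lognormal measurement noise,
  LOQ censoring) for power and design exploration.

## The model in brief

A barcode candidate is a peptide `F_N · c · F_C` with constant 6-mer flanks
and a variable 5-mer core *c*. Its monoisotopic mass is
`M(p) = Σᵢ m(pᵢ) + m(H₂O)`, precursor m/z at charge *z* is
`(M + z·m_H⁺)/z`, and the fragment series are
`bᵢ = Σ_{k≤i} m(p_k) + m_H⁺`, `y_j = Σ_{k>n−j} m(p_k) + m(H₂O) + m_H⁺`.
Two barcodes are MS1-resolvable when `|M₁ − M₂| ≥ Δ₁` and
MS2-distinguishable when some b/y ion differs by `≥ Δ₂`.

Quantitation: for animal *a* with peak areas `A_{a,i}`, the fold change of
barcode *i* relative to reference *r* is `FC_{a,i} = A_{a,i} / A_{a,r}`;
LNPs are ranked by group mean fold change, and rankings are compared with
the exact Wilcoxon matched-pairs signed-rank test (full enumeration of the
2ⁿ sign assignments; no normal approximation).

The simulator draws
`A_{a,i} = E_i(d_i) · α_a · ε_{a,i}` with `E_i` a Hill curve
`emax·d^h/(ed50^h + d^h)` and `α, ε` unit-mean lognormals — the shared
animal factor `α_a` is exactly cancelled by reference normalization.

## Worked example

```sh
python examples/design_panel.py
```

prints

```
allowed alphabet: AFGHILPSTVY
enumerated cores: 161,051
exactly one proline: 50,000
a 120-member panel is resolvable at an MS1 separation of 0.0503 Da (band up to 0.0503 Da)
first three members:
  GGGGP  GSGSGAGGGGPAGSGSG  1175.4803 Da
  AGGGP  GSGSGAAGGGPAGSGSG  1189.4959 Da
  AAGGP  GSGSGAAAGGPAGSGSG  1203.5116 Da
```

161,051 is the full 11⁵ core space; 50,000 survive the exactly-one-proline
rule; calibration then finds the precursor-mass tolerance (≈0.05 Da) at
which 120 barcodes remain mutually resolvable on mass alone. The other
examples (`digest_verify.py`, `mrna_orf.py`, `quant_ranking.py`,
`simulate_screen.py`) walk the remaining stages; `quant_ranking.py`
recovers the LNP potency order `MC3 > KC2 > C12-200 > DLin-DMA > DOTAP`
from a simulated five-LNP pool.

A thin CLI mirrors the same stages
(`pals design|digest|mrna|quant|simulate --help`).

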