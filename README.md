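# pyrocall

Pyrosequencing pyrogram analysis for clinical hotspot mutation testing:
EGFR (codons 719, 746–753, 768, 790, 858), KRAS (codons 12/13, 61) and
BRAF (codon 600).

Pyrosequencing reports a *pyrogram*: one light peak per dispensed
nucleotide, with height proportional to the number of bases incorporated.
Reading a pyrogram by hand means juggling the dispensation order, the
wildtype peak pattern, every catalog mutation's pattern, and the unknown
tumor fraction — a sophisticated manual process where errors happen.
`pyrocall` automates it for molecular-lab workflows: it simulates expected
peak patterns for wildtype/mutant mixtures, recognizes which catalog
mutation a measured pyrogram contains, quantifies the mutant percentage,
and annotates every peak as wildtype, mutant, mixed or noise.

## Model

For an assay with dispensation order of length *n*, wildtype expected
pattern **w** and mutant pattern **m** (per-copy units, from a run-length
walk of the read along the order), a specimen with mutant fraction *f*
produces

    h_i = (1 − f)·w_i + f·m_i + noise,        i = 1…n

after normalizing instrument units by B, the mean height of the
single-incorporation reference peaks. For each catalog variant *f* has a
closed-form least-squares estimate (clipped to [0, 1]); candidates are
ranked by rms residual. Peaks below twice the mean height at the assay's
zero-signal ("unexpected") dispensations are treated as non-specific noise.
A mutation is called only when the estimated percentage strictly exceeds
the 5% sensitivity threshold. The EGFR exon-21 L858R percentage is also
available through the published peak formula
`[(1/3)·A/B + (1 − C/B) + (1 − D/E)]/3 × 100`, which coincides with the
least-squares estimate on ideal data. BRAF V600K, whose pyrogram differs
from V600E only subtly, gets a dedicated two-standard-deviation reference
rule. See `docs/methods.md` for the full treatment.

## Worked example

Simulate an exon-21 specimen with 55% L858R at instrument scale 200, then
analyze it:

```sh
pyrocall synth --assay EGFR_ex21 --variant L858R --fraction 0.55 \
    --scale 200 --out l858r.tsv
pyrocall analyze --assay EGFR_ex21 --input l858r.tsv
```

```
assay: EGFR_ex21
call: mutation-detected
mutation: L858R (detected)
mutant percent: 55.0 (threshold 5.0)
QC:
  reference B: 200
  reference SD: 0
  noise cutoff: 0
  wildtype rms: 0.55

disp	base	observed	wildtype	mutant	label
1	A	0.00	0.00	0.00	Absent
2	C	200.00	90.00	110.00	Mixed
3	G	330.00	0.00	330.00	Mut
4	T	90.00	90.00	0.00	WT
5	G	180.00	180.00	0.00	WT
6	T	0.00	0.00	0.00	Absent
7	C	400.00	180.00	220.00	Mixed
8	A	600.00	270.00	330.00	Mixed
...
```

The G peak at dispensation 3 (height 330) exists only because of the T→G
mutation; the T and G peaks at dispensations 4–5 come only from the
remaining wildtype allele; reference peaks such as dispensation 2 carry
both alleles. Plugging the printed peak heights into the formula —
A=330, B=200, C=90, D=180, E=400 — returns the same 55.0%.

The same works from Python:

```python
import numpy as np
from pyrocall import Pyrogram, call_specimen, get_assay

assay = get_assay("KRAS_12_13")
heights = [0, 0, 40.89, 133.11, 87, 0, 0, 174, 0, 0, 0, 0,
           87, 87, 87, 87, 174, 87, 0, 0, 0, 0, 0]
result = call_specimen(Pyrogram(assay.order.bases, np.array(heights)), assay)
print(result.call, result.variant_id, round(result.mutant_percent, 1))
# mutation-detected G12C 47.0
```

Pyrograms are plain TSV (`disp	base	height`); assay catalogs are JSON
(`pyrocall catalog list | show | validate`) and user catalogs can extend or
replace the built-in one.

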