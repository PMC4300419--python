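# Curation of the bundled 86-compound solubility table

The bundled fixture (`biosol/data/table1.csv`) is a curated transcription of a
published compilation of apparent solubility (S_app, log10 molar) for 86
lipophilic drugs in three media: blank phosphate buffer pH 6.5 (PhB),
fasted-state simulated intestinal fluid (FaSSIF) and aspirated human
intestinal fluid (HIF), together with molecular weight, predicted
logD at pH 6.5, polar surface area, rotatable-bond count, melting
point, and the training/test (Tr/Te) label used for the FaSSIF model.

## Parsing conventions

The printed table fuses adjacent columns. Numbers were split using the
conventions confirmed by the table's own Min/Max/Median rows:

- MW, logD, PSA and Tm carry one decimal; rotatable bonds are integers;
  solubilities carry two decimals (one row prints a PhB value of -4.9).
- Unicode minus signs were normalised to ASCII hyphens.

## Assignment of missing media

Every compound has a FaSSIF value (the compilation is the FaSSIF dataset).
45 rows print all three solubilities and are unambiguous. 20 rows print a
single value, which is therefore FaSSIF. 21 rows print two values; the
missing medium is either PhB or HIF and is not marked typographically.
The assignment below is pinned by internal consistency:

1. The HIF dataset comprises 48 compounds, so exactly 3 of the 21
   two-value rows carry FaSSIF+HIF.
2. The printed PhB maximum (-2.19, quinidine) and HIF maximum (-2.02)
   force **Ibuprofen** (-2.17, -2.02) to be FaSSIF+HIF: were -2.17 a PhB
   value it would exceed the printed PhB maximum.
3. Among the remaining choices, assigning **Cilostazole** (-4.77, -4.76)
   and **Phenytoin** (-3.81, -3.77) to FaSSIF+HIF reproduces the printed
   PhB median (-4.38) exactly and the printed HIF median (-4.00, computed
   -4.005) at printed precision, and is most consistent with the printed
   global inter-medium correlations.

The other 18 two-value rows are PhB+FaSSIF: Amitriptyline, Cisapride,
Digoxin, Disopyramide, Haloperidol, Indoprofen, Ivermectin, Lansoprazole,
Loperamide, Lorazepam, Nevirapine, Panadiplon, Phenazopyridine, Pranlukast,
Praziquantel, Rofecoxib, Terfenadine, Tolfenamic acid.

With this curation the fixture reproduces the printed summary rows
(all Min/Max/Median values for MW, logD, PSA, rotatable bonds, Tm, and the
three media at printed precision) and the dataset counts
(86 compounds, 56 Tr, 48 with HIF, 63 with PhB).

## Known residual discrepancies

- The source text states PhB solubility was available for 76% of the
  compounds; the curation pinned by HIF n=48 gives 63/86 = 73%. No
  assignment consistent with the printed Max rows can reach 76%.
- The published inter-medium correlation figures (r² 0.61/0.62/0.78 and
  logD-stratified 0.82/0.28) are not recomputable from the printed table
  under any assignment of the ambiguous rows; they most plausibly include
  a proprietary 26-compound discovery set measured in all three media that
  is not part of the printed table. The values computed from the fixture
  are reported by `scripts/acceptance.py`.
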