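# venomics

Downstream analysis of venom peptidomics: reconstruction and mass-based
validation of mature venom toxins from multi-enzyme digests and native
precursor-ion maps, Hi3 label-free quantification, physicochemical
profiling, and bioactivity-screening decision rules.

## Who this is for

Venom-gland studies identify toxin *precursors* (signal peptide +
propeptide + mature region) from transcriptome-guided MS/MS searches, but
the biologically active species is the secreted mature peptide — often
disulfide-stabilized, sometimes post-translationally modified. This
package implements the computation between the identification software
and the biology:

* **chemistry** — exact monoisotopic mass and m/z arithmetic with
  disulfide correction (−2 × 1.0078250319 Da per S-S bond) and a small
  PTM catalog (carbamidomethyl, oxidation, deamidation, N-terminal
  acetylation, C-terminal amidation with glycine-donor loss);
* **digestion** — in silico proteolysis with trypsin, chymotrypsin,
  Glu-C, Asp-N and thermolysin, with missed-cleavage and semi-specific
  expansion matching typical search settings (≤2 missed, ≤1 nonspecific
  terminus);
* **assembly** — per-residue coverage of parents by identified peptides,
  mature N-terminus calling by multi-enzyme boundary consensus, and the
  overlapping-fragment criterion for "fully sequenced";
* **validation** — intensity filtering (≥5.0×10⁵), neutral-mass
  clustering of redundant precursor ions, theoretical +2..+9 charge
  ladders, and 10-ppm matching of candidate mature masses against the
  native ion map;
* **physchem** — Henderson–Hasselbalch net charge vs pH, isoelectric
  point, and amino-acid class composition with Cys exclusion for
  disulfide-bonded peptides;
* **quantification** — Hi3 abundance (mean of the three most intense
  peptides), identification filters (≥3 peptides, ≥2 replicates), and
  relative abundance;
* **screening** — threshold rules over external antimicrobial/anticancer
  predictor scores (significant AMP activity: score > 0.8; ACP label:
  both anticancer scores > 0.5);
* **synthetic** — a seeded generator of precursors, digests and ion maps
  for end-to-end testing without instrument data.

The package ships the published reference tables for the
*Acanthoscurria rondoniae* venom (18 validated mature toxins, the
33-protein quantification table, predictor scores, and composition
values) under `venomics.datasets`.

## Worked example

```python
from venomics.datasets import load_reference_toxins
from venomics.physchem import net_charge, isoelectric_point
from venomics.validation import theoretical_ladder

toxins = {t.id: t for t in load_reference_toxins()}
u3 = toxins["U3-TRTX-Ar1a"]          # 48-residue CRP, 3 disulfide bonds

print(round(u3.theoretical_mass(), 2))            # 5439.75
print(round(net_charge(u3.mature_sequence, 7.4), 2))  # 5.94
print(isoelectric_point(u3.mature_sequence))      # 10.6
for z, mz in theoretical_ladder(u3.theoretical_mass(), 2, 5):
    print(z, round(mz, 3))
# 2 2720.88
# 3 1814.256
# 4 1360.944
# 5 1088.956
```

The theoretical mass (5439.75 Da; printed observed value 5439.80 Da,
≈10 ppm apart) is the disulfide-corrected monoisotopic mass the
validation stage matches against decharged native precursor ions. The
net charge of +5.94 at pH 7.4 (Cys excluded — the six cysteines are
engaged in the three S-S bonds) and the isoelectric point of 10.6 mark
this toxin as strongly cationic at physiological pH, the property that
underlies its high predicted antimicrobial activity. The ladder rows are
the m/z values at which the intact toxin appears at charges +2..+5.

A complete run — filter → cluster → coverage → consensus → validate →
physchem → quant → screen — is available both as a library call
(`venomics.io.run_pipeline`) and as a CLI:

```bash
venomics simulate --seed 5 --outdir fixtures/
venomics run --toxins mature.fa --ssbonds ss.tsv --ions ions.tsv --out out/
```

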