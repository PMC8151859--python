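# lipidfc

An untargeted lipidomics analysis pipeline for cell-culture treatment
studies: it annotates LC–MS features against a theoretical lipid mass
library, normalizes peak areas by the number of cells extracted, imputes
left-censored values below the limit of detection, and estimates treatment
effects as bootstrap log fold changes with percentile confidence intervals —
per lipid species and per lipid family. It ships a synthetic-study generator
with known ground truth, so the whole chain can be validated end to end
without any instrument data.

The intended user is an analyst comparing drug-treated against
vehicle-treated cultures (the motivating design: three liver cancer cell
lines treated with the anthracyclins doxorubicin and idarubicin at doses
causing >50% mortality, against DMSO-matched vehicles, in three culture
replicates), who wants interval estimates of lipidome remodeling — such as
increases in polyunsaturated fatty acids (PUFAs) and ether
glycerophosphoethanolamines (etherPEs) carrying PUFAs — rather than
p-values.

## The statistics at the core

For each lipid (or lipid family) and each (cell line, drug) the effect is
the **log fold change**

&nbsp;&nbsp;&nbsp;&nbsp;log FC = ln ( x̄<sub>treated</sub> / x̄<sub>vehicle</sub> ),

where x is the peak area per extracted cell. Uncertainty comes from
**B = 10,000 bootstrap resamples**: each draw resamples both groups with
replacement at their own sizes and recomputes the statistic; the central
estimate is the mean of the draws and the 95% interval their 2.5th/97.5th
percentiles.

Values under the limit of detection are **left-censored**: a lipid's
detected areas are fitted to a normal distribution and each missing value is
drawn from that normal truncated below the minimum detected signal (and
above zero). Comparisons with more than one censored value in either group
are discarded. Feature identity comes from the m/z of the expected adducts
(|Δm/z| ≤ 10 ppm), refined to fatty-acyl combinations from the [FA−H]⁻
carboxylate fragments in MS2, with free-fatty-acid isomers assigned by
mammalian abundance priors (the dominant FA(18:1) peak is oleic acid,
FA(18:1n-9)).

## Worked example

Simulate the default study (451 lipid species across 18 families, 3 cell
lines × 2 drugs × 3 replicates, QC pool every fifth injection) and run every
stage:

```python
from lipidfc import PipelineConfig, run_pipeline
import pandas as pd

cfg = PipelineConfig(outdir="lipidfc_out", seed=1, bootstrap=10_000)
run_pipeline(cfg)

fc = pd.read_csv("lipidfc_out/foldchanges.tsv", sep="\t", comment="#")
ether = fc[(fc.level == "family") & (fc.name == "etherPE")]
print(ether[["cell_line", "drug", "central", "ci_low", "ci_high"]]
      .round(2).to_string(index=False))
```

which prints

```
cell_line drug  central  ci_low  ci_high
    HepG2  DOX     0.29    0.00     0.54
    HepG2  IDA     0.47    0.40     0.54
     Huh7  DOX     0.52    0.41     0.64
     Huh7  IDA     0.42    0.26     0.58
   SNU449  DOX     0.28    0.07     0.48
   SNU449  IDA     0.38    0.09     0.66
```

The generator injects a true ln(1.5) ≈ 0.41 increase on every
PUFA-containing etherPE species; the family-level intervals recover it in
all six conditions with every lower bound above zero (HepG2/DOX prints 0.00
after rounding; the computed bound is positive). The cell-count summary from
the same run shows the designed mortality:

```
cell_line drug  reduction_pct
    HepG2  DOX           60.6
    HepG2  IDA           52.2
     Huh7  DOX           59.9
     Huh7  IDA           58.4
   SNU449  DOX           56.3
   SNU449  IDA           62.1
```

The same run is available from the shell:

```sh
lipidfc all --out lipidfc_out --seed 1
lipidfc simulate --fixtures --out fixtures --seed 1   # small test bundle
```

Outputs are plain TSV/CSV with a seed-stamped comment header, plus a
`manifest.json` recording stage status and SHA-256 hashes of every file;
two runs with the same seed are byte-identical.

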