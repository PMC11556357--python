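# binocgain

Binocular contrast gain control modelling: dipper functions, dichoptic
masking, synthetic 2IFC observers, and hierarchical Bayesian fitting.

## What this is for

How the brain combines the two eyes' signals is usually probed with
contrast discrimination ("dipper") experiments: an observer detects a
target increment on a pedestal shown monocularly, binocularly,
half-binocularly or dichoptically. The characteristic pattern of
thresholds across these arrangements — binocular summation at
detection, converging monocular/binocular handles, very strong
dichoptic masking — is captured by a two-stage gain control model with
interocular suppression before binocular summation:

    Stage1_L = C_L^m / (S + C_L + ω·C_R)        (and mirror for R)
    Stage2   = binsum^p / (Z + binsum^q),        binsum = Stage1_L + Stage1_R

Thresholds solve `Stage2(target+pedestal) − Stage2(pedestal) = k`, and
`d′ = (response difference)/(k/τ)` with `τ = Φ⁻¹(0.75)·√2 ≈ 0.954`.
A three-pathway extension adds cross-pathway interocular suppression
between the achromatic, L-M and S-(L+M) mechanisms to model dichoptic
masking within and between chromatic pathways.

The package is aimed at visual psychophysicists who want to simulate
these designs, fit the model to 2IFC trial data (simplex on thresholds
or hierarchical Bayesian on trial-level binomial data), and regenerate
the standard dipper and masking analyses end to end on synthetic data.

## Worked example

```python
from binocgain import MEESE_2006, OcularArrangement, dipper_curve, summarize_dipper

peds = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
mono = dipper_curve(peds, OcularArrangement("monocular"), MEESE_2006)
bino = dipper_curve(peds, OcularArrangement("binocular"), MEESE_2006)
dich = dipper_curve(peds, OcularArrangement("dichoptic"), MEESE_2006)

print([round(t, 3) for t in mono.thresholds])
print(summarize_dipper(bino, ref_curve=mono))
print(round(summarize_dipper(dich)["handle_slope"], 3))
```

prints

```
[1.348, 0.849, 0.427, 0.414, 0.9, 1.527, 2.47, 3.902]
{'summation_ratio': 1.4961343584856182, 'facilitation_factor': 3.723440408717676, 'handle_slope': 0.6698171036213557}
1.088
```

The monocular detection threshold is 1.35 normalized units, dipping to
0.41 at low pedestals (facilitation) before rising along the masking
handle. Binocular detection is better than monocular by the summation
ratio 1.50 ≈ 2^(1/m) for m = 1.28, and the dichoptic handle has the
near-unity log-log slope (1.09) that is the signature of strong
interocular suppression.

The same machinery runs from the shell:

```bash
binocgain simulate --config exp2.yaml --seed 1 --out trials.csv   # 72,000 trials
binocgain fit trials.csv --seed 1 --out report.json               # elevation matrix, fits
binocgain reproduce --table table1_simplex --seed 1 --out repro.json
```

where `exp2.yaml` contains `experiment: exp2`. The fit report includes
the 3×3 threshold-elevation matrix (rows = target pathway, columns =
mask pathway), whose diagonal dominance reflects stronger
within-pathway than cross-pathway dichoptic masking.

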