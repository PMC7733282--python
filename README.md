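# plaquefir

Label-free FTIR imaging analysis of amyloid-beta (Aβ) plaque types in
brain tissue.

Alzheimer's disease plaques occur in distinct morphologies — diffuse,
compact, and classic cored — thought to represent successive stages of
Aβ fibrillation. Infrared microspectroscopy can resolve this process
chemically: the protein Amide I band (C=O stretch, ~1700–1600 cm⁻¹)
encodes secondary structure, with the main β-sheet component near
1630 cm⁻¹ shifting toward 1628–1620 cm⁻¹ as parallel β-sheets extend
into fibrils, while antiparallel β-sheets add a minor marker near
1693 cm⁻¹. `plaquefir` implements the full analysis chain that turns
hyperspectral FTIR absorbance cubes of tissue sections, plus a
co-acquired anti-Aβ immunostain (IHC) image, into per-plaque
spectroscopic metrics and cohort statistics:

1. **Quality control** — per-pixel SNR rule (Amide I maximum over
   detrended silent-region noise, threshold 100) and scattering rule
   (silent-region mean ≤ A₁₆₅₅/2); failing pixels are excluded, never
   imputed.
2. **EMSC Mie correction** — extended multiplicative signal correction
   with a van de Hulst scattering basis removes the oscillatory
   baselines that tissue scattering adds to IR microspectra.
3. **Registration** — a landmark-based 2D affine warps the IHC image
   onto the spectral cube's pixel grid.
4. **Masking** — Otsu's threshold on the warped stain defines the
   Aβ-positive plaque mask; a 100 µm distance-transform ring (minus
   Aβ-positive pixels) defines the surrounding tissue.
5. **Core segmentation** — hierarchical cluster analysis (Ward,
   k = 10) of a cored plaque's spectra, with automated merging of
   high-β-ratio clusters into the core.
6. **Amide analysis** — linear baselines, area normalization,
   difference spectra, Savitzky–Golay second derivatives (order 3,
   window 5), band picking with parabolic refinement, and the two
   headline ratios: protein accumulation A₁₅₄₅/A_CH and β-sheet level
   A₁₆₃₀/A₁₆₅₅.
7. **Statistics** — Student's t-test ladder along the development
   sequence (control → diffuse → compact → classic cored → core) with
   significance stars, Pearson correlation of the two ratios, boxplot
   summaries with the 1.5·IQR outlier rule.

Because matched human-tissue data cannot ship with the code, the
package includes a first-class synthetic scene generator
(`plaquefir.synthetic_scene`) producing hyperspectral cubes with known
ground truth — gray-matter band composition, the three plaque
morphologies, oligomer-vs-fibril Amide I mixtures, ester-depleted
cores, Mie baselines, noise, and a misaligned pseudo-IHC image — so
every stage is testable against truth. See `docs/methods.md` for the
models and all numerical choices.

## Worked example

Simulate one classic cored plaque, run the whole chain, and look at
the per-compartment metrics:

```python
import plaquefir as pf
from plaquefir.cli_pipeline import RunConfig, analyze_scene

cfg = RunConfig(
    scene=pf.single_plaque_config("classic_cored", seed=1),
    n_control_patches=2, control_patch_um=12, make_figures=False,
)
df, report, art = analyze_scene(cfg)
print(df[["group", "protein_ratio", "beta_ratio",
          "beta_position_cm1", "n_pixels"]].round(2).to_string(index=False))
print(f"registration RMS residual: {art['registration_rms']:.2e} px")
```

```
        group  protein_ratio  beta_ratio  beta_position_cm1  n_pixels
classic_cored           5.54        1.05            1629.08       815
         core           7.43        3.09            1628.11        95
      control           4.45        0.38            1632.80       118
      control           2.65        0.39            1632.80       118

registration RMS residual: 3.40e-14 px
```

Reading the numbers: the whole-plaque spectrum (core + corona) shows
moderately elevated protein and β-sheet levels over gray-matter
controls, while the HCA-extracted core is strongly β-sheet enriched
(β ratio 3.1 vs 0.38 in controls) with its second-derivative β band at
1628.1 cm⁻¹ — the position of extended parallel β-sheet fibrils —
compared to ~1630 cm⁻¹ for oligomer-dominated diffuse deposits. The
registration residual is at machine precision because the landmarks
are exact in simulation.

The same chain is scriptable from the shell:

```sh
plaquefir simulate --seed 5 --out scene.h5
plaquefir qc --cube scene.h5 --out qc.csv
plaquefir run-all --seed 5 --out out/    # full chain + stats + figures
```

`run-all` writes `out/{cube,masks,segmentation,metrics,stats,figures}`
with a `run_log.json` carrying the config echo, seed and library
versions; re-running with the same seed reproduces all numeric outputs
byte-identically.

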