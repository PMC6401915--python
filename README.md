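# cdshape

Conformational shape analysis of (hydroxypropyl-)β-cyclodextrin
ensembles.

β-cyclodextrin (βCD) is a macrocycle of seven α-d-glucopyranose units
whose hydrophobic cavity encapsulates poorly water-soluble guests.
Hydroxypropyl (HP) substitution at the O2/O6 hydroxyls improves
solubility but changes the cavity's shape — glucose units flip, the
ring distorts elliptically, and HP groups can rotate *into* the cavity
and block it (cavity self-closure).  `cdshape` is a library for people
who study these effects from multi-frame structures (REMD/MD snapshots
or synthetic ensembles): it computes the standard per-frame shape
descriptors, aggregates them into ensemble statistics, and ships a
synthetic conformer generator plus a toy replica-exchange sampler so
the whole pipeline can be exercised — and validated against exact
ground truth — without any trajectory data.

## Descriptors and statistics

With 1-based cyclic unit index *i* (unit 8 ≡ unit 1 for βCD):

| quantity | definition |
|---|---|
| d1(i) | O2(i)–O3(i+1) distance (secondary-rim hydrogen-bond belt), Å |
| d2(i) | O4(i)–O4(i+1) glycosidic-oxygen distance (ellipticity), Å |
| d3(i) | C_g(Glu(i))–O4(i+3) cross-cavity diameter (unit-COM to opposite glycosidic O), Å |
| θ(i)  | C6(i)–C2(i+1)–C6(i+1) angle; a pair with θ > 90° marks a glucose flip |
| d4(j) | C_g(ring)–C_g(HP(j)) distance; d4 < 3 Å defines an inserted HP |
| Rg    | √(Σ mᵢ‖rᵢ−r_cm‖² / Σ mᵢ), mass-weighted radius of gyration, Å |
| C     | min d3(i) / max d3(i), circularity ∈ (0, 1]; C = 1 ⇔ circular cavity |

Ensemble level: the (d1, d2) pair histogram is Boltzmann-inverted into
a free-energy surface F(x, y) = −k_B T log P(x, y) (k_B =
0.0019872041 kcal mol⁻¹ K⁻¹, F in kcal/mol); flip populations are
percentages of frames by counted-angle number; n(HP_inserted) =
n(d4 < 3 Å) per frame gives the self-closure distribution and the
closure percentage P(n > 0).

## Worked example

```python
import json
import cdshape as cs

# 2,000-frame ensemble of a singly HP-substituted CD: 60% open
# (HP pointing outward, d4 ≈ 8 Å) and 40% self-closed (HP in the
# cavity, d4 ≈ 1.5 Å), with 0.05 Å coordinate noise.
mixture = cs.closure_mixture(closure_fraction=0.4)
ensemble, topology, truth = cs.generate_ensemble(
    mixture, n_frames=2000, noise_sigma=0.05, seed=42
)
metrics = cs.metrics_table(ensemble, topology)
print(json.dumps(cs.summarize(metrics, temperature=300.0), indent=2))
```

prints

```json
{
  "temperature_K": 300.0,
  "n_frames": 2000,
  "flip_population_pct": {
    "0": 100.0
  },
  "circularity_mean": 0.9856262919598019,
  "circularity_sd": 0.004375125457468135,
  "rg_mean_A": 5.273049175645718,
  "self_closure": {
    "probability_by_n_inserted_pct": {
      "0": 59.75,
      "1": 40.25
    },
    "closure_percentage": 40.25
  }
}
```

No frame was built with a flipped unit, so 100% of frames sit in the
no-flip class; the recovered closure percentage (40.25%) agrees with
the generating fraction (40%) within binomial sampling error; the mean
circularity is just below 1 because coordinate noise slightly breaks
the ideal sevenfold symmetry.

The same pipeline runs from the shell on files
(`cdshape synth | analyze | fes | remd | report`); `analyze` reads
multi-model PDB or XYZ plus a YAML topology that maps atom names (or
indices) to the per-unit roles O2/O3/O4/C2/C6 and to HP groups, and
writes a per-frame metrics TSV, a summary JSON and the FES grid.

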