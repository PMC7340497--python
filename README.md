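# smlmkit

Quantitative analysis of single-molecule localization microscopy (SMLM)
experiments on membrane protein complexes. The package was built around the
workflows used to characterize the γ-secretase protease (PSEN1/NCT/APH1/PEN2)
at the plasma membrane, but every stage is generic:

* **Colocalization** — nearest-neighbor distances between two channels of
  resolved spot centroids, with an empirical randomized control built by
  pairing non-corresponding cells, association fractions below 100 nm /
  50 nm, and spot densities.
* **Stoichiometry** — subunit copy numbers per spot from photobleaching
  step counting (penalized change-point segmentation) and from
  intensity-histogram decomposition into a unit distribution and its
  self-convolution, with closed-form correction for the ~20% of
  fluorescent-protein tags that are dark:
  `f₂ = f_d·p²/(f_d·(1−(1−p)²)+(1−f_d)·p)`, inverted as
  `f_d = f₂/(p−f₂(1−p))`.
* **Motility** — per-track time-averaged MSD; diffusion coefficient
  `D = slope/4` from the first four MSD points; anomaly exponent from the
  power-law fit `MSD(t) = Γ·t^α + k`; five-class motility assignment
  (immobile `D ≤ 0.01 µm²/s`, then confined / anomalous / Brownian /
  directed by α).
* **Hotspots** — DBSCAN nanodomains (ε = 80 nm, minPts = 20, ≥ 18
  localizations), convex-hull areas, diffraction-limited projection masks
  with Pearson/Mander's overlap, and track–hotspot association.
* **Simulators** — every input above with planted ground truth, including
  exact fractional-Brownian-motion trajectories, so estimators are
  validated by recovery.

Audience: microscopists and analysts who have localization tables, track
tables, or spot-intensity traces (Thunderstorm-style CSV and friends) and
want the published quantities recomputed reproducibly.

See `docs/methods.md` for models, assumptions, and numerical choices.

## Worked example

Classify a simulated sptPALM experiment: 500 tracks of 50 frames at
0.05 s/frame, 87% mobile Brownian molecules at D = 0.15 µm²/s, 13%
immobile, 16 nm localization error.

```python
from smlmkit import MotilityClassifier, expected_visible_two_fraction
from smlmkit.simulate import TrackSimParams, generate_tracks

tracks, truth = generate_tracks(
    n_tracks=500,
    class_weights=(0.13, 0.0, 0.0, 0.87, 0.0),   # immobile : Brownian
    params=TrackSimParams(diffusion_coefficient=0.15, immobile_diffusion=0.001),
    n_frames=50,
    seed=7,
)
clf = MotilityClassifier().fit(tracks)
print(f"mobile fraction : {clf.mobile_fraction_:.3f}")
print(f"mean alpha      : {clf.mean_alpha_:.3f}")
print(f"mean D (mobile) : {clf.results_.loc[clf.results_.d_coef > 0.01, 'd_coef'].mean():.3f} um^2/s")
print(f"expected visible dimer fraction at p=0.8: {expected_visible_two_fraction(0.8, 1.0):.3f}")
```

```
mobile fraction : 0.854
mean alpha      : 1.004
mean D (mobile) : 0.149 um^2/s
expected visible dimer fraction at p=0.8: 0.667
```

The classifier recovers the planted mobile share (0.854 vs the 0.87
generating weight, within the binomial spread of 500 draws), the Brownian
exponent (α ≈ 1), and the planted diffusion coefficient. The last line is
the dark-fraction arithmetic: an all-dimeric population tagged with a
fluorophore that is 80% fluorescent shows only ~67% visibly double spots.

Estimators follow scikit-learn conventions (`get_params`/`set_params`,
fitted attributes with trailing underscores): `SpotAssociation`,
`IntensityMixtureModel`, `BleachStepCounter`, `MotilityClassifier`, and
`HotspotDetector` (a `ClusterMixin` with `labels_`). Module-level functions
(`nearest_neighbor_distances`, `fit_two_component`, `compute_msd`,
`dbscan_hotspots`, …) are thin wrappers over them.

A CLI drives the same stages on files or simulated inputs:

```bash
smlmkit simulate --seed 1 -o out/    # synthetic inputs + truth sidecars
smlmkit dynamics --tracks out/tracks.csv -o out/
smlmkit hotspots --locs out/localizations.csv --dialect thunderstorm -o out/
smlmkit all --seed 1 -o out/         # every stage + JSON reports + manifests
```

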