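# fixartifact

Does chemical fixation faithfully preserve liquid–liquid phase separation
(LLPS) as it looks in a living cell?  Paraformaldehyde cross-links proteins
at rates comparable to — or slower than — the binding and dissociation
dynamics of droplet-like nuclear puncta, so a fixed cell can over- or
under-represent the punctate appearance of a phase-separating protein.
`fixartifact` provides the computational toolkit for studying this
quantitatively:

* **Kinetic model of fixation.**  A protein of interest exchanges between
  an in-puncta state S1 and a dilute state S2 (binding rate k1, dissociation
  rate k2, all rates in s⁻¹).  Fixative opens two irreversible channels,
  S1 → S3 at rate k3 and S2 → S4 at rate k4, with S1+S2+S3+S4 = 1 mol/L.
  The artifact statistic is

  ΔPunctatePercentage = 100·S3(∞)/(S3(∞)+S4(∞)) − 100·S1(0)/(S1(0)+S2(0)),

  evaluated exactly from the 2×2 linear transient generator (no long
  integration).  Phase-diagram sweeps show the three-way interplay of
  starting punctate percentage, relative in-puncta fixation rate k3:k4 and
  relative overall fixation rate (k3+k4):(k1+k2).

* **Puncta quantification.**  Three projection-based image parameters per
  nucleus: number of puncta (ImageJ-style prominence/"noise tolerance"
  maxima inside the nucleus mask), surface roughness (standard deviation of
  normalized nuclear intensity), and punctate percentage (fraction of
  sum-projection fluorescence inside disks of diameter FWHM, the FWHM taken
  as the maximum over 36 radial slices per punctum).  Live/fixed pairs are
  compared as per-cell percent changes.

* **SPT residence times.**  In-puncta single-molecule trajectories
  (classified by the fraction F of localizations inside puncta masks:
  F > 50 % in, F < 5 % out) yield dwell-time survival curves fitted to
  P(t) = A·e^(−t/τ_ns) + (1−A)·e^(−t/τ_s); the specific residence time τ_s
  is photobleach-corrected against an immobile H2B reference via
  τ_corrected = 1/(1/τ_s − 1/τ_H2B).

* **Synthetic data with ground truth** for every stage, and the Wilcoxon
  signed-rank / rank-sum tests used for paired image metrics and two-group
  residence comparisons.

## Worked example

```python
>>> import fixartifact as fa

# A protein at 50% starting punctate percentage, exchange k1+k2 = 0.3/s,
# fixed twice as fast outside puncta as inside (k3=1, k4=2 /s):
>>> model = fa.FourStateModel.from_equilibrium(50, 0.3, k3=1.0, k4=2.0)
>>> res = model.artifact(50)
>>> round(res.final_punctate_percentage, 2), round(res.delta, 2)
(46.94, -3.06)
```

Fixation here *diminishes* the apparent LLPS by 3.06 percentage points:
46.94 % of the protein ends up cross-linked in puncta although 50 % was in
puncta in the live cell.  With k3 = k4 the artifact is exactly 0 for any
starting percentage, and at a 1000-fold faster overall fixation rate the
same 1:2 imbalance leaves only |Δ| ≈ 0.037 pp.

Residence-time recovery on synthetic single-molecule data:

```python
>>> from fixartifact import synth, spt
>>> spec = synth.SyntheticDwellSpec(A=0.5, tau_ns=2.0, tau_s=10.0,
...                                 tau_bleach=100.0, n=5000, seed=42)
>>> dwells, _ = synth.make_dwell_times(spec)
>>> fit = spt.SurvivalModel.from_dwells(dwells).fit()
>>> round(fit.tau_s, 2)          # apparent (bleach-shortened)
9.06
>>> round(fit.correct(100.0).tau_corrected, 2)   # true residence time
9.96
```

The same stages are scriptable from the shell (`fixartifact simulate`,
`sweep`, `quantify`, `compare`, `spt`, `synth`, `run`); see `--help`.

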