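# capiflow

Capillary-flow phantom and discretization-error analysis for
one-compartment perfusion estimation.

## The problem

Perfusion maps (CBF, in ml/min/100ml) from CT or MR bolus-tracking are
computed voxel by voxel with one-compartment (1C) tracer-kinetic models —
deconvolution of the tissue curve against an arterial input function, or
the maximum-slope method. Both assume the analyzed region is an isolated
compartment with its own arterial supply. A voxel of capillary tissue is
not: it is fed by its neighbours and feeds them in turn. Dividing a
voxel's inflow by the voxel's volume normalizes the flow to the wrong
distribution volume, so voxelwise perfusion estimates are *discretization
dependent* — the same tissue yields different numbers at different voxel
sizes. `capiflow` is for researchers in perfusion imaging who want to
quantify that error under controlled conditions.

## What it computes

The package builds a continuous reference model — steady Darcy flow
`q = −(k/μ)∇p` through a porous slab with corner source and sink, plus the
indicator-dilution transport `φ ∂c/∂t + ∇·(c q) = c_a Q_so + c Q_si`
integrated by donor-cell upwinding — and evaluates the classic estimators
against two ground truths:

* **Local perfusion** `P_v = (1/|Ω|)∫_{S_in} |q·n| dA` — boundary inflow
  per control volume; well defined but scale dependent.
* **Streamline perfusion** `P_s = (∫₀ˡ r(u)² du)⁻¹` with `r² = 1/|q|`
  along each arterial-to-venous streamline (traced by FACT) — constant
  along a streamline, equal to `φ/T` by the central volume theorem, and
  independent of discretization.
* **Reconstructions**: block-circulant truncated-SVD deconvolution
  (`P = max_t I`), maximum slope (`P = max C′ / max c_a`), and the CBV
  area ratio `φ = ∫C/∫c_a`, applied voxelwise after block-averaging the
  simulated movie to voxel sizes from 0.047 to 3 mm.

No external data is required; everything is generated internally. A thin
adapter applies the same estimators to user-supplied 4D concentration
arrays.

## Worked example

```sh
python examples/05_discretization_error.py
```

runs the full study on the default phantom (64×64 cells, 3 mm field of
view, mean perfusion 50 ml/min/100ml, porosity 0.05) and prints:

```
voxel size | mean bSVD | mean MS | RE(bSVD,Ps) | RE(MS,Ps) | CBV RE
   [mm]    |   [ml/min/100ml]    |        [%]              |  [%]
   0.047   |     87.6  |  101.7  |      94.1   |   122.1   | 0.0000
   0.094   |     87.2  |  101.3  |      92.3   |   119.9   | 0.0000
   0.188   |     86.2  |   99.9  |      87.9   |   114.5   | 0.0000
   0.375   |     83.8  |   96.3  |      78.9   |   102.7   | 0.0000
   0.750   |     78.8  |   88.6  |      63.1   |    81.2   | 0.0000
   1.500   |     70.3  |   75.5  |      41.0   |    50.5   | 0.0000
   3.000   |     54.3  |   49.8  |       8.7   |     0.2   | 0.0000
```

Read bottom-up: applied to the whole region of interest (3 mm) both
estimators recover the true 50 ml/min/100ml within 10%; every subdivision
inflates the estimates — roughly a factor two at full resolution — purely
through discretization, while blood volume (CBV) stays accurate at every
scale. The streamline ground truth itself is scale stable: its map mean is
49.95 ml/min/100ml at full resolution and varies < 1% under block
averaging. The local ground truth at a single cell, e.g.
`P_v(32,35) = 5328 ml/min/100ml`, shows how extreme voxel-level
"perfusion" becomes when the flow through one 0.047 mm cell is normalized
by that cell's volume.

See `docs/methods.md` for the model, its assumptions and numerical
choices.

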