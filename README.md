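# mfdlab

Single-molecule multiparameter fluorescence and binding-thermodynamics
analysis for detecting **minor, transiently released conformational
states in tight protein complexes**.

The motivating system is the intrinsically disordered Cdk2 inhibitor
p27 bound to Cdk2/cyclin A: although the complex is picomolar-tight,
p27's inhibitory subdomain must transiently release from the kinase so
that its buried tyrosines (Y88, Y74) can be phosphorylated — the event
that reactivates Cdk2 and triggers p27 degradation.  Detecting a
sparsely populated (~tens of percent), rapidly exchanging released
state requires analyses that separate conformational heterogeneity
from photon shot noise, and binding thermodynamics that count how many
residues actually fold upon binding.  `mfdlab` implements that
tool-chain end to end, together with a synthetic-data generator that
makes every stage testable against known ground truth.

## What it computes

**Burst-wise MFD observables** (`bursts`): burst search on time-tagged
4-channel photon streams; per burst or per Δt time window the
FRET-averaged donor–acceptor distance
⟨R_DA⟩_E = R0·(γ·F_D/F_A)^(1/6), the fluorescence-weighted donor
lifetime ⟨τ_D(A)⟩_f (mono-exponential MLE with IRF convolution), and
the scatter-corrected anisotropy r_D.

**Shot-noise PDA** (`pda`): probability distribution analysis predicts
the *full histogram* of ⟨R_DA⟩_E or r_D from k Gaussian states
(mean, half-width, fraction) convolved with the binomial counting
noise of the measured per-window photon totals, and fits k-state
models globally across Δt = 1, 2, 3 ms windows.  Because shot-noise
broadening is predicted rather than fitted, excess histogram width is
direct evidence for conformational heterogeneity.

**Static FRET lines and the dynamic shift** (`fretmodel`): the locus
of static single-distance molecules in the ⟨R_DA⟩_E-vs-⟨τ_D(A)⟩_f
plane (published coefficient sets built in); populations shifted to
the long-lifetime side of the line are the hallmark of exchange faster
than the observation window.  Also the Perrin equation
r = r0/(1+τ/ρ) and its inverse for rotational correlation times.

**Filtered FCS** (`ffcs`): species filters from TCSPC decay patterns,
species auto-/cross-correlation on a multi-tau photon-pair correlator,
and diffusion × relaxation fits — anticorrelated sCCF terms yield the
exchange relaxation times (ns–ms).

**ITC thermodynamics** (`thermo`): exact 1:1 isotherm fits with
dilution bookkeeping, ΔG = RT·ln K_D, −TΔS = ΔG − ΔH, ΔCp from the
ΔH(T) series, and the Spolar–Record dissection
ℜ = [ΔS_assoc − 1.35·ΔCp·ln(T/386 K) − ΔS_rt] / ΔS_res, the number of
residues that fold upon binding.

**Accessible volumes & SASA** (`avsim`): grid/Dijkstra dye-cloud
simulation on PDB structures predicting ⟨R_DA⟩_E for comparison with
smFRET, and Shrake–Rupley relative solvent accessibility.

**Synthetic data** (`simkit`): photon streams of freely diffusing
molecules with k-state Markov exchange, Förster colour statistics,
Perrin polarisation, TCSPC micro times and Poisson background
(Photon-HDF5-style container I/O), plus synthetic ITC titration
series — all exactly reproducible from a seed.

## Worked example

Simulate 300 s of a two-state smFRET measurement — a major compact
state (45 Å, 83%) in slow exchange with a minor released state
(52 Å, 17%), R0 = 53 Å — then recover the states by global
three-window PDA:

```python
import numpy as np
import mfdlab as m
from mfdlab import pda

hf = m.DyeState("bound",    R_DA=45.0, sigma_DA=2.0, tau_D=4.0, rho=2.0)
lf = m.DyeState("released", R_DA=52.0, sigma_DA=2.0, tau_D=4.0, rho=2.0)
model = m.ExchangeModel((hf, lf),
                        np.array([[-2.0, 2.0], [9.76, -9.76]]), R0=53.0)
conf = m.ConfocalModel(mean_occupancy=0.02, brightness=120.0, background=0.2)
stream = m.simulate_photon_stream(model, conf, 300.0, seed=1)

bursts = m.find_bursts(stream)
bins = np.linspace(30, 80, 62)
datasets = []
for dt in (1.0, 2.0, 3.0):
    windows = []
    for i, b in enumerate(bursts):
        windows += m.time_windows(stream, b, dt, i)
    datasets.append(pda.pda_data_from_windows(
        windows, "fret", bins, R0=53.0, label=f"dt={dt}ms"))

fit = pda.pda_fit(datasets, k_states=2, seed=0)
print(f"{len(bursts)} bursts, "
      f"{int(sum(d.n_windows for d in datasets))} time windows")
for s in fit.model.states:
    print(f"  state at {s.mean:4.1f} A  half-width {s.half_width:3.1f} A"
          f"  fraction {s.fraction:.2f}")
print(f"chi2_r = {fit.chi2_r:.2f}")
```

Output:

```
2514 bursts, 7012 time windows
  state at 45.1 A  half-width 2.0 A  fraction 0.84
  state at 51.9 A  half-width 1.9 A  fraction 0.16
chi2_r = 0.85
```

The fit recovers the simulated means within fractions of an Ångström
and the 83/17 population split within 1%, with a reduced χ² of ~1 —
the histogram broadening beyond the two Gaussian states is fully
accounted for by shot noise.

On the thermodynamics side:

```python
from mfdlab import thermo
dG = thermo.free_energy(4.9e-9, 298.15)          # -11.34 kcal/mol
mTdS = thermo.entropy_term(dG, -50.6)            # +39.26 kcal/mol
thermo.residues_folded(-1267.0, mTdS, 298.15).R_fold   # ~93 residues fold
```

## Documentation

`docs/methods.md` describes the generative model, every estimator, the
numerical choices and the known limitations.
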