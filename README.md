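# pmfrelease

Free-energy-based prediction of hydrophobic-drug release from polymer
matrices, at desk scale.

Sustained-release formulations load a hydrophobic drug (or a prodrug
conjugate — an oleic-acid or PEG tail changes everything) into a polymer
matrix such as PLGA, and the release rate is governed by thermodynamics: how
deep is the free-energy well the compound sits in, relative to bulk water?
`pmfrelease` implements the computational side of that question end to end
for people who develop or teach these methods — umbrella sampling with WHAM
reconstruction of the translocation free-energy profile, MBAR alchemical
solvation/transfer free energies and log P_ow, bottom-up coarse-grained
bonded-parameter fitting, conversion of barriers to relative release rates
with Ritger–Peppas curve fitting, and contact-cutoff aggregation analysis —
with one twist: a built-in stochastic-dynamics toy engine on analytic
potentials replaces the MD package, so every estimator can be exercised,
seeded, and tested against a planted ground truth in minutes on a laptop.

## The models

**Translocation profile and barrier.** Umbrella windows restrain the
drug–matrix distance z with biases w_j(z) = ½k(z−c_j)² (protocol: 60
windows, 0.2 nm spacing, k = 1000 kJ·mol⁻¹·nm⁻²). WHAM recombines the
biased histograms,

    p(z) ∝ Σᵢ nᵢ(z) / Σⱼ Nⱼ exp(β(Fⱼ − wⱼ(z))),   Fⱼ = −k_BT ln Σ_z p(z) e^{−βwⱼ(z)},

giving G(z) = −k_BT ln p(z) referenced to the aqueous plateau, with bootstrap
error bars. The translocation barrier ΔG_t* = min G − ⟨G⟩_water (≤ 0) is the
depth of the compound's preferred location; deeper ⇒ slower release, and
with equal diffusivities two compounds' rates compare as
k_a/k_b = exp(β(ΔG_a − ΔG_b)).

**Alchemical free energies.** Samples from a λ schedule (soft-core
Lennard–Jones decoupling, Beutler form, finite at r = 0) feed the MBAR
self-consistency f_i = −ln Σₙ exp(−u_in)/Σₖ Nₖ exp(f_k − u_kn), yielding
ΔG_solv = k_BT(f₁ − f₀) with asymptotic standard errors, transfer free
energies between solvents, and log P_ow = ΔG_{O→W}/(2.303 RT).

**Release kinetics.** Cumulative release follows the Ritger–Peppas law
M_t/M_∞ = K·tⁿ, fitted on the early-release region (≤ 60% released), where
n ≈ 0.43–0.5 signals Fickian diffusion.

**Aggregation.** Drug molecules in a periodic box cluster by single-linkage
contacts at minimum-image distance ≤ 0.6 nm; number- and mass-averaged
cluster sizes are tracked per frame.

See `docs/methods.md` for assumptions, numerical choices, and what the
synthetic tests do and do not establish.

## Worked example

Recover a planted 69.8 kJ/mol translocation well through the full umbrella
protocol, then rank the drug/prodrug series:

```python
import numpy as np
from pmfrelease import (
    LangevinConfig, make_translocation_potential, generate_umbrella_dataset,
    bootstrap_pmf_error, extract_barrier, rank_compounds, relative_rate,
)

potential = make_translocation_potential(
    well_depth=-69.8, well_center=3.0, interface_center=7.0, interface_width=1.0
)
config = LangevinConfig(n_steps=2_000_000, seed=42, diffusion_coeff=0.004)
windows = generate_umbrella_dataset(
    potential, np.arange(0.0, 11.81, 0.2), spring=1000.0, config=config,
    equilibration_steps=5000, sample_stride=1000,
)
profile = bootstrap_pmf_error(windows, n_boot=16, seed=43)
barrier = extract_barrier(profile)
print(f"dG_t* = {barrier.delta_g:.1f} +/- {barrier.stderr:.1f} kJ/mol "
      f"at z = {barrier.minimum_location:.2f} nm")

series = {"DTXL": -69.8, "OA-DTXL": -75.3, "PEG10-DTXL": -76.9, "PEG25-DTXL": -90.7}
print(" > ".join(rank_compounds(series).order))
print(f"k(DTXL)/k(PEG25-DTXL) = {relative_rate(-69.8, -90.7, 310.0):.0f}")
```

Output:

    dG_t* = -68.0 +/- 2.1 kJ/mol at z = 2.90 nm
    DTXL > OA-DTXL > PEG10-DTXL > PEG25-DTXL
    k(DTXL)/k(PEG25-DTXL) = 3323

The recovered barrier agrees with the planted −69.8 kJ/mol within its
bootstrap error (2000 samples per window here; the protocol-scale tests use
more). The free drug ranks fastest and the long-PEG conjugate slowest, and
the rate ratio shows how strongly a 21 kJ/mol barrier difference suppresses
escape at 310 K.

The same pipeline runs from the shell:

    pmfrelease demo --seed 2024 --out run/
    pmfrelease release rank --barriers "DTXL=-69.8,OA-DTXL=-75.3,PEG10-DTXL=-76.9,PEG25-DTXL=-90.7"

`pmfrelease demo` writes `report.json`, per-compound PMF tables, release-fit
results and a cluster trace under `run/`, with every seed recorded; two runs
with the same seed are byte-identical. Subcommands `toysim`, `wham`, `mbar`,
`release`, `clusters` and `cgfit` expose each module individually.

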