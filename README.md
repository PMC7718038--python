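# phagekit

A toolkit for characterizing lytic bacteriophages, built around the
classical workflow for a newly isolated phage: one-step growth-curve
kinetics, in-silico restriction analysis of a circularly permuted
genome, consensus-rule genome feature annotation, and distance-based
phylogenetics. It is aimed at phage biologists and bioinformaticians
who want each of those computations as tested, scriptable pieces rather
than a chain of web servers, plus a forward infection simulator and a
synthetic genome generator so every stage can be exercised end to end
without any downloads.

## What it computes

**One-step growth kinetics** (`phagekit.kinetics`). From a free-phage
titer time series P(t) (PFU/mL) in a culture of N bacteria (CFU/mL):

- multiplicity of infection, MOI = (V_p · T_p) / (V_c · N);
- adsorption rate constant from two time points,
  k = −ln(P(t₁)/P(t₀)) / (N · (t₁ − t₀)), in mL·min⁻¹, conventionally
  with t₀ = 0 and t₁ = 4 min;
- latency period L: the earliest sampled time whose log₁₀ titer rises
  significantly (μ + max(3σ, log₁₀ rise-factor) over the
  post-adsorption baseline) and persistently above baseline;
- burst size B = P(t_burst) / (P(0) − P(t_adsorb)) — progeny per
  adsorbed phage, read just after the first infection cohort has lysed.

The `OneStepGrowth` model / `OneStepGrowthResults` pair wraps these in
a fit-and-summarize interface with plotting.

**Infection simulation** (`phagekit.simulate`). A well-mixed adsorption
+ delayed-lysis model, dP/dt = −k(S+I)P with infections at rate kSP, a
fixed or gamma-distributed lysis delay, optional secondary infection by
progeny, deterministic (cohort recursion) and stochastic (exact event /
tau-leaping) integrators, and a Poisson dilution-plating observation
model.

**Genome features** (`phagekit.features`, `phagekit.synthgenome`).
GC content, IUPAC restriction-site mapping and digestion for linear,
circular and headful-packaged (circularly permuted virion pool)
topologies, σ⁷⁰ promoter consensus scanning (TTGACA — 17 nt spacer —
TATAAT), Shine–Dalgarno RBS detection (AGGAGG, 5–9 nt upstream of the
start codon), RBS-gated ORF calling, a rho-independent terminator
heuristic, and a generator for random genomes with planted,
ground-truthed features.

**Phylogenetics** (`phagekit.phylo`). p-distances with pairwise
deletion, Saitou–Nei neighbor joining with deterministic tie-breaking,
bootstrap supports from column resampling, affine-gap global percent
identity, and Newick I/O.

## Worked example

Simulate a one-step growth experiment at a realistic operating point
for a fast T1-like coliphage (k = 8.5×10⁻¹⁰ mL·min⁻¹, latency 14 min,
burst 13, MOI 0.14), observe it through triplicate Poisson dilution
plating, and re-estimate the parameters:

```python
import phagekit as pk

params = pk.SimulationParameters(seed=11)   # defaults are the operating point
series = pk.simulate_titer_experiment(params, noise=True, n_replicates=3,
                                      target_count=1000, seed=11)
inoculum = pk.InoculumSpec(phage_volume_ml=1.0, phage_titer=2.5e9,
                           culture_volume_ml=44.0, bacterial_density=4e8)
print(pk.OneStepGrowth(series, inoculum).fit().summary())
```

```
          One-step growth curve analysis
==================================================
MOI                             0.14
Adsorption rate constant k      8.6e-10 mL/min
Adsorbed fraction (0-4 min)     0.746
Latency period                  14 min
Burst size                      12 PFU/cell
Burst read at                   16 min
==================================================
```

The recovered MOI is the exact inoculum arithmetic; k lands within a
few percent of the simulated 8.5×10⁻¹⁰ (plating noise plus two
significant figures of display rounding); the latency is recovered on
the 2-min sampling grid; and the burst estimate sits slightly below
the simulated 13 because the burst quotient divides by *adsorbed*
phage, a few percent of which land on already-infected cells and
produce nothing (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
phagekit simulate --seed 11 --noise --out growth.tsv
phagekit kinetics --titers growth.tsv --phage-volume 1 --phage-titer 2.5e9 \
    --culture-volume 44 --cell-density 4e8
phagekit digest --fasta genome.fasta --enzymes SacI,ApaI --topology circular
phagekit phylo --alignment aln.fasta --bootstrap 500 --seed 17 --out tree.nwk
```

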