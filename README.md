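# cyclopep

Energy-based design tools for cyclic peptide backbones at desk scale.

Mid-sized cyclic peptides (7–24 residues, head-to-tail amide bond, mixed
L/D chirality) are attractive therapeutics: rigid, specific, resistant to
degradation. Designing them computationally requires sampling *closed*
backbone conformations — a hard constraint that random torsion sampling
almost never satisfies — and then judging whether a designed structure is
the dominant low-energy state of its sequence. `cyclopep` implements a
complete torsion-space pipeline for both problems:

- **Exact cyclic-closure error.** With ideal bond lengths/angles and a
  trans peptide bond, a backbone is a function of its (φ, ψ) torsions.
  Walking local coordinate frames around the ring gives a per-residue
  rotation `M_i = T(θ_C′) R(ω) T(θ_N) R(φ_i) T(θ_Cα) R(ψ_i)` and a
  torsion-independent displacement `q = [3.5620, 1.3322, 0]ᵀ` Å, and the
  scalar

  `E_cyc = ‖q + M₁q + … + M₁⋯M_{n−1}q‖² + ‖M₁⋯M_n e₁ − e₁‖² + ‖M₁⋯M_n e₂ − e₂‖²`

  vanishes exactly when the ring closes with matching terminal frame.
  A damped Gauss–Newton solve drives `E_cyc` to machine precision from
  nearby starts.
- **Layered simulated annealing.** Per-residue disk moves in Ramachandran
  space pass an ordered battery of Metropolis tests — Ramachandran energy,
  steric repulsion, cyclic error, H-bond energy (plus the remaining pair
  terms for small rings) — so expensive terms are only computed for moves
  that survive the cheap ones. Closed, clash-free, well H-bonded states
  are recorded as good backbone candidates.
- **Torsion-bin clustering.** Each residue maps to one of six Ramachandran
  bins; candidates are grouped by their bin string modulo cyclic rotation
  (canonical form = lexicographically smallest rotation), keeping the
  lowest-energy representative, with
  `E_total = 0.45·E_rama + E_rep + E_hbond + E_other`.
- **Stability analysis.** The folding-funnel statistic
  `PNear = Σᵢ exp(−RMSDᵢ²/λ²) exp(−Eᵢ/kT) / Σⱼ exp(−Eⱼ/kT)`
  (kT = 0.62 kcal/mol; λ = 0.5 / 1.5 / 2.0 Å by size class; PNear > 0.9
  indicates stability) over landscapes built either by Ramachandran
  threading of a sequence onto the backbone pool (small rings) or by
  **ClusterGen**, a genetic algorithm with SA-seeded populations, window
  crossover/mutation gated on re-closure, manifold-descent relaxation, and
  greedy energy-ordered RMSD clustering (published population schedules:
  500; 750−5i; 1000−10i over 50 generations).
- **Analytics.** Kabsch RMSD minimized over all cyclic residue
  relabelings, landscape reshaping onto the sampled energy minimum,
  backbone RMS radius, H-bond chord-intersection counts, and free-energy
  surfaces `F = −RT ln P(RMSD, R_g)` on a 50×50 histogram.

## Worked example

Count the rotation-unique six-bin starting assignments for a 7-ring, then
sample one good backbone and score it:

```python
>>> from cyclopep import count_unique_initial_configurations, step_vector
>>> count_unique_initial_configurations(7)
39996
>>> step_vector().round(4)
array([3.562 , 1.3322, 0.    ])

>>> from itertools import islice
>>> from cyclopep import enumerate_initial_configurations, sample_backbones
>>> from cyclopep.config import get_profile
>>> prof = get_profile("7")
>>> starts = list(islice(enumerate_initial_configurations(7, seed=0), 200))
>>> cands = sample_backbones(starts, prof.schedule(), prof.criteria(),
...                          seed=1, stop_after=1)
>>> c = cands[0]
>>> c.bin_string, c.hbond_count, f"{c.breakdown.cyclic_err:.1e}"
('1454432', 2, '2.2e-22')
```

The candidate occupies bin classes 1-4-5-4-4-3-2 around the ring, closes
to numerical precision, and carries two strong backbone H-bonds — a
"good backbone" by the recording criteria. PNear from a landscape table is
one call (or `cyclopep pnear --landscape table.tsv` from the shell):

```python
>>> from cyclopep import pnear
>>> pnear(energies=[0.0], rmsds=[0.5], lambda_=0.5, kT=0.62)
0.36787944117144233
```

The same functionality is exposed by the `cyclopep` CLI:
`sample`, `cluster`, `landscape`, `pnear`, `filterscan`, `predict`,
`fes`, and `count-configs`.

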