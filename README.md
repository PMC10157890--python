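# kdacsel

Substrate-selectivity mapping for metal-dependent lysine deacetylases
(KDACs/HDACs, EC 3.5.1.98).

KDACs remove the ε-N-acetyl mark from acetyllysine (Kac) in proteins, and
which substrates an individual KDAC prefers is largely decided by the
residues flanking the acetyllysine.  `kdacsel` implements, as a tested
reusable pipeline, the analysis chain that links molecular-dynamics (MD)
simulations of enzyme–acetylpeptide complexes to measured deacetylation
activity:

1. **Interaction fingerprinting** — on multi-model PDB trajectories, four
   geometric interaction types are scored per enzyme residue × substrate
   position (offsets …−1, +1, +2 relative to Kac = 0) in every frame:
   - *total contact*: any atom pair ≤ 0.30 nm;
   - *ionic*: cationic-group hydrogen ≤ 0.25 nm from an anionic-group oxygen;
   - *H-bonds* (side-chain/side-chain and side-chain/backbone): donor and
     acceptor heavy atoms ≤ 0.35 nm with the H–D–A angle ≤ 30°.

2. **Frequency aggregation** — percent of simulation time per interaction,
   averaged over five replicate trajectories and truncated to integer
   percent (lower limit 1%).  Interactions seen only while the substrate is
   out of the catalytically relevant pose (Zn²⁺-to-acetyl-carbonyl distance
   > 0.32 nm) are excluded, as are interactions averaging < 1% over all
   peptides capable of forming them.

3. **Two-stage selectivity statistics** — *substrate clusters* (peptides
   sharing one or two residues of {A,E,R,W,Y} at +1 or +2) are tested per
   enzyme residue and interaction type with pooled two-sample t-tests
   (Bonferroni-corrected, p ≤ 0.01), and passing clusters are tested for an
   activity difference with a two-sided Mann–Whitney U (p ≤ 0.05).
   Frame-level co-occurrence of interactions uses a log-space two-sided
   Fisher exact test (p-values below double underflow stay representable),
   and interaction–activity relations use Pearson correlation.

4. **Activity panels and kinetics** — normalization of specific activities
   (s⁻¹) to a reference peptide (FRKacWR ≡ 1), pairwise two-tailed t-test
   matrices with Bonferroni correction, ratio error propagation,
   Michaelis–Menten fits (v₀ = k_cat·[E]·[S]/(K_M+[S]); K_M in μM, k_cat in
   s⁻¹, efficiency k_cat/K_M in M⁻¹s⁻¹), and Fisher-exact validation of
   residue preferences against detectable activity.

A seeded synthetic-data module generates every input shape the pipeline
consumes — trajectories with planted two-state Markov interaction episodes,
activity panels with planted cluster effects, and kinetic timecourses — so
all stages are testable offline.  Two published validation panels (30
peptides for KDAC6, 29 for KDAC8, derived from human proteins with known
acetylation sites) ship as packaged CSV fixtures.

## Worked example

Fit steady-state kinetics from a synthetic timecourse generated at the
reference parameters of the FRKacWR peptide (K_M = 28 μM, k_cat = 0.23 s⁻¹)
with 5% multiplicative noise:

```python
>>> from kdacsel.synthetic import generate_timecourses
>>> from kdacsel.kinetics import MichaelisMenten
>>> df = generate_timecourses(28.0, 0.23, 100.0, noise_sd=0.05, seed=42)
>>> print(MichaelisMenten.from_timecourses(df, enzyme_conc=100.0).fit().summary())
Michaelis-Menten fit
============================================
K_M                26.88 ± 2.3        uM
k_cat             0.2306 ± 0.011      1/s
k_cat/K_M           8578 ± 4.2e+02    1/(M s)
[E]                  100 nM
n([S])                 7
```

The fit recovers the planted K_M within one standard error; the efficiency
is reported in M⁻¹s⁻¹ (0.2306 / 26.88e-6 ≈ 8578).

Validate the predicted KDAC6 preference for aromatic +1 residues on the
packaged 30-peptide panel:

```python
>>> from kdacsel import datasets
>>> from kdacsel.activity import residue_presence_fisher, aromatic_plus1
>>> table, p = residue_presence_fisher(datasets.kdac6_panel(), aromatic_plus1)
>>> table.tolist(), round(p, 3)
([[10, 0], [10, 10]], 0.011)
```

All ten peptides with Y/W/F directly after the acetyllysine were
deacetylated, versus ten of twenty without — a significant association
(two-sided Fisher exact p = 0.011) between the aromatic +1 residue and
KDAC6 activity.

The same workflow is available from the shell:

```sh
kdacsel validate-preferences --panel kdac6
kdacsel simulate traj --spec spec.json --seed 7 --out traj/
kdacsel interactions --traj 'traj/*.pdb' --kac 3 --out freqs/
kdacsel report --traj-dir runs/ --activities panel.csv --kac 3 --out report/
```

## Documentation

`docs/methods.md` describes the interaction definitions, exclusion rules,
statistical procedures, the synthetic-data model and its limitations, and
the numerical choices made throughout.
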