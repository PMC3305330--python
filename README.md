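# memcrowd

Entropic tensions and gating energetics of membrane proteins in crowded
membranes.

Biological membranes carry protein area fractions of roughly 20–55%, dense
enough that excluded-area interactions between membrane proteins shift the
free-energy balance of any conformational change that alters a protein's
in-plane footprint. `memcrowd` models the crowding proteins as a
two-dimensional fluid of hard disks and computes the crowding contribution
to the gating free energy of a protein — the case study is the bacterial
mechanosensitive channel MscL, a disk whose radius switches from 2.4 nm
(closed) to 3.5 nm (open) — together with the resulting shift of its gating
tension and open-probability curve. It is aimed at membrane biophysicists
who want quantitative, closed-form estimates of crowding effects, plus an
independent Monte Carlo check of the theory.

## Model

All energies are in units of k<sub>B</sub>T and lengths in nm. A crowder
mixture is a discrete set of disk radii *r<sub>i</sub>* with relative
abundances, total number density *c* (nm⁻²), area fraction
φ = cπ⟨r²⟩ and relative radius variance
δ² = (⟨r²⟩ − ⟨r⟩²)/⟨r⟩². Crowding acts on a gating transition through an
entropic **surface tension** σ<sub>c</sub> conjugate to the channel's area
change ΔA = π(R<sub>o</sub>² − R<sub>c</sub>²) and an entropic **line
tension** τ<sub>c</sub> conjugate to its circumference change
ΔC = 2π(R<sub>o</sub> − R<sub>c</sub>):

| model | σ<sub>c</sub> (k<sub>B</sub>T/nm²) | τ<sub>c</sub> (k<sub>B</sub>T/nm) |
|---|---|---|
| ideal gas | c | c⟨r⟩ |
| SPT, uniform crowders | c/(1−φ)² | cr/(1−φ) |
| SPT, mixture | c[1/(1−φ) + φ/((1+δ²)(1−φ)²)] | c⟨r⟩/(1−φ) |

where SPT is scaled-particle theory for hard-disk mixtures. In the
**constant-area** ensemble both tensions act,
ΔG<sub>crowd</sub> = σ<sub>c</sub>ΔA + τ<sub>c</sub>ΔC. In the
**constant-tension** ensemble (the appropriate one for patch-clamp
experiments on MscL) the membrane area grows with the channel so the
surface-tension term cancels: ΔG<sub>crowd</sub> = τ<sub>c</sub>ΔC, with a
loading-device relaxation −σΔA. The two-state open probability is
P<sub>open</sub>(σ) = 1/(1 + e<sup>ΔG</sup>) with
ΔG = (σ*₀ − σ)ΔA + τ<sub>c</sub>ΔC, so crowding moves the gating midpoint
up by τ<sub>c</sub>ΔC/ΔA.

A hard-disk Metropolis Monte Carlo sampler with Widom test-particle
insertion (periodic box, minimum image) provides an independent numerical
estimate of the SPT insertion free energy
μ<sub>ex</sub>(R) = −ln p<sub>insert</sub>.

## Worked example

A membrane whose area is half proteins: uniform 1 nm crowders at φ = 0.5
(c = 0.5/π ≈ 0.159 nm⁻²), MscL opening 2.4 → 3.5 nm:

```bash
memcrowd gating --config examples/mscl.yaml
```

```
ensemble,model,crowding_energy_kT,gating_tension_shift_kT_per_nm2,...
constant_area,ideal_gas,4.3,0.21,...
constant_area,spt,15.2,0.74,...
constant_tension,ideal_gas,1.1,0.05,...
constant_tension,spt,2.2,0.11,...
```

Reading: at fixed membrane area, crowding opposes opening by 4.3
k<sub>B</sub>T in the dilute (ideal-gas) estimate and 15.2 k<sub>B</sub>T
once crowder–crowder exclusion is resummed by SPT — at φ = 0.5 SPT
enhances the surface and line tensions by factors of exactly 4 and 2
(`memcrowd tensions` prints σ = 0.637 vs 0.159, τ = 0.318 vs 0.159). At
fixed applied tension only the line tension survives, leaving 1.1 and 2.2
k<sub>B</sub>T. The corresponding gating-tension increases (crowding
energy divided by ΔA ≈ 20.4 nm²) are 0.21/0.74/0.05/0.11 k<sub>B</sub>T/nm²,
to be compared with bare MscL gating tensions of 0.3–1.3 k<sub>B</sub>T/nm²:
crowding alone can shift the midpoint by a sizeable fraction of the gating
tension itself.

Other subcommands: `popen-curve` (open-probability curves and midpoints),
`mixture-stats`, `mc-validate` (SPT vs Widom Monte Carlo), `make-fixture`
(seeded synthetic crowder tables, including transmembrane-helix-count
abundance TSVs converted to radii via r ∝ √n).

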