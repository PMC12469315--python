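# cuspec

Solution-equilibrium analysis of copper(II) with tyrosine and adenine
nucleosides/nucleotides: a mass-balance speciation solver, a potentiometric
titration simulator, a stability-constant refinement engine and
equilibrium-constant bookkeeping, with the published constant sets for five
systems bundled as ready-made models.

## Who this is for

Coordination and bioinorganic chemists who work with glass-electrode
titrations and overall stability constants (log β) — the HYPERQUAD/HySS
style of workflow — and want a scriptable, testable Python counterpart for:

* computing **species distribution diagrams** from a set of log β values,
* **simulating titration curves** (pH vs added NaOH, with dilution),
* **refining log β** from titration curves by nonlinear least squares and
  ranking candidate species models,
* deriving **stepwise equilibrium constants** (log Ke) from overall
  constants by Hess-type additivity.

## The model

A speciation model lists components (Cu²⁺, ligands, H⁺) and species
M<sub>m</sub>L<sub>l</sub>H<sub>h</sub> with overall formation constants on
the molar concentration scale:

```
beta_mlh = [M_m L_l H_h] / ([M]^m [L]^l [H]^h)
```

Hydroxide is carried as H₋₁ (so hydrolysis species such as Cu(OH)₂ have
negative log β), and all constants are conditional at the stated medium
(here 0.1 M KNO₃, 20 °C; no activity corrections). At fixed pH the free
concentrations solve the component mass balances

```
T_j = f_j + Σ_i ν_ij · 10^(log β_i) · Π_k f_k^ν_ik
```

by damped Newton–Raphson iteration in log-space; a titration point
additionally solves the proton condition
`T_H = [H] − Kw/[H] + Σ_i ν_iH c_i` for the pH. Refinement minimizes
`Σ = Σ_i w_i (pH_obs,i − pH_calc,i)²` over all curve points by
Levenberg–Marquardt, with pH_calc from full titration simulation.

Bundled systems: `Cu_Tyr`, `Cu_Tyr_Ado`, `Cu_Tyr_AMP`, `Cu_Tyr_ADP`,
`Cu_Tyr_ATP` (binary Cu/tyrosine, and ternary with adenosine, AMP, ADP,
ATP; each ternary model carries the ligand protonation ladders, the binary
Cu complexes and Cu(OH)₂ hydrolysis it needs).

## Worked example

```python
import cuspec

model = cuspec.bundled_model("Cu_Tyr")
diagram = cuspec.distribution(model, {"Cu": 1e-3, "Tyr": 2e-3})

print(cuspec.peak(diagram, "CuH(Tyr)"))
print(cuspec.dominant_species(diagram, 10.2))
print(cuspec.log_ke(model, cuspec.parse_reaction(
    "CuH(Tyr) + H(Tyr) = CuH2(Tyr)2")))
```

prints

```
(4.83, 70.72270510595978)
CuH(Tyr)2
6.5600000000000025
```

meaning: the monoprotonated 1:1 complex CuH(Tyr) binds at most 70.7 % of
total copper (at pH 4.83) when 1 mM Cu(II) is titrated with 2 mM tyrosine;
at pH 10.2 the bis-complex CuH(Tyr)₂ is the predominant copper species; and
attaching a second H(Tyr) to CuH(Tyr) has log Ke = 35.38 − 18.54 − 10.28 =
6.56, exactly the difference of the stored overall constants.

Short narrative scripts, one per capability, live in `examples/`. A thin
command-line interface mirrors the library:

```sh
cuspec ke --model Cu_Tyr --reaction "CuH(Tyr) + H(Tyr) = CuH2(Tyr)2"
cuspec distribution --model Cu_Tyr --total Cu=1e-3 --total Tyr=2e-3 \
       --range 2.5:11:0.01 --out dist.tsv
cuspec synth --system Cu_Tyr --n-curves 6 --sigma 0.005 --seed 1 --out study/
cuspec refine --model Cu_Tyr --study study/ \
       --free "CuH2(Tyr)" "CuH(Tyr)" "CuH2(Tyr)2" "CuH(Tyr)2"
```

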