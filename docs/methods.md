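# Methods

## Model structure and assumptions

The simulator describes (part of) a root system as *n* well-mixed
compartments characterised only by cumulative root length. It deliberately
ignores branching topology, root diameter, the main/lateral root
distinction, shoot growth and soil nitrate depletion: shoot leaf area —
and hence photosynthetic carbon supply — is assumed proportional to total
root length, which makes unregulated growth exponential,
L(t) = L(0)·e^(conv·r·t). All pools are amounts (μmol) and every
concentration is normalised per mm of root length: local concentrations by
the compartment's length, systemic ones by the total root length. External
nitrate per compartment is a fixed boundary condition (μmol/L).

State variables per compartment: length L_x, internal nitrate N_i,x, local
CEP and CK amounts. Systemic variables: nitrate N_s, CEP_s, CK_s. Local
nitrate enters by saturating high-affinity plus linear low-affinity uptake
and drains to the systemic pool; the systemic pool loses a zeroth-order
maintenance flux u_m·ΣL and a first-order exudation flux e·N_s. CEP
production falls with local external nitrate (a starvation/demand signal),
CK production rises with it (a supply signal); both are exported to their
systemic pools, which degrade slowly.

## Regulatory layers

Growth-rate regulation is multiplicative; each layer can be toggled, and
the `L0`…`L7` presets add them in the order the model was assembled:

| layer      | function | form | interpretation |
|------------|----------|------|----------------|
| basic      | f_basic([N_s]) | 0.5 + 0.5·Hill₂(K=0.04) | survival response; the 0.5 floor stands in for stored nitrate the model does not track |
| local      | f_local(N_e) | 0.65 + 0.35·Hill₂(K=200) | NRT1.1-type local stimulation; baseline 0.65 without nitrate |
| cep        | f_CEP | 1 + 0.5·Hill₂([CEP_s]; K=1)·g_NE | demand-driven boost, gated by local nitrate presence g_NE = Hill₂(N_e; K=750) |
| systrepr   | f_systrepr([N_s]) | K⁴/(K⁴+[N_s]⁴), K=0.4 | systemic repression at nitrate excess |
| systfor    | f_systfor([N_s]) | 1 + K⁴/([N_s]⁴+K⁴), K=0.12 | foraging boost at moderately low systemic nitrate |
| carbon     | g_carbon | r_x·L_x/Σr_y·L_y | sink-strength competition for carbon |
| ck_gating  | g_CK([CK_s]) | 0.1 + 0.9·Hill₂(K=2) | supply signal modulating demand-signal efficacy |

The three systemic-nitrate responses act at deliberately separated
concentrations (0.04 / 0.12 / 0.4 μmol/mm), which is why the maintenance and
exudation constants are set to spread systemic nitrate over a wider range
than local nitrate.

## Parameters

Defaults live in `ModelParameters` and are the published parameterization:
uptake up1 = 0.6 μmol·mm⁻¹·h⁻¹, K_up = 75 μmol/L, up2 = 6·10⁻⁶
L·mm⁻¹·h⁻¹, T_up = 3.8 h⁻¹, u_m = 0.1 μmol·mm⁻¹·h⁻¹, e = 1.5 h⁻¹,
conv = 0.01; CEP and CK production/transport/degradation 0.1 / 0.1 / 0.001
(h⁻¹ scale) with half-saturations K_CEP = 250 and K_CK = 750 μmol/L; the
regulatory amplitudes and half-saturations as tabulated above. Notes:

- **K_up ambiguity.** The sources give both 50 and 75 μmol/L for the
  half-saturation of high-affinity uptake; the default is 75, and 50 is one
  config line away (`parameters: {K_up: 50}`). The steady-state fit check
  reports residuals under both; with 75 the worst residual against the
  converted reference nitrate contents is 0.014 μmol/mm.
- **a_basic** is dimensionless (0.5) even though one source table attaches
  h⁻¹ to it; it is a fraction inside f_basic.
- **Mutants** are parameter overrides: *nrt1.1* pins f_local at 0.6 and
  scales up1 by 0.8; *cep* and *ck* zero p_CEP or p_CK.

## Calibration arithmetic

`calibration` reproduces the parametrization chain: reference root nitrate
contents (48/45/39 mg per g dry weight at 11400/550/275 μmol/L external
nitrate, plus a value at 110 μmol/L extrapolated from the shoot content 29
via a 1.1 shoot:root ratio → 26) are converted to μmol per g fresh weight
(÷4 fresh:dry ratio, ÷62.0049 g/mol) and then to μmol per mm root length
(÷1.2 g fresh weight per cm). The chain yields 0.194/0.181/0.157/0.105
μmol/g fw and 0.161/0.151/0.131/0.087 μmol/mm. The growth conversion factor
solves 720 mm = 20 mm·e^(conv·1.5 h⁻¹·240 h) → conv = ln 36/360 ≈ 0.00995,
used as 0.01. `fit_check` is a regression guard, not a fitting routine: it
compares the model's closed-form internal-nitrate steady states (unit-length
single root) to the converted targets and reports residuals.

## Experiment conditions

- **Dose–response**: single compartment, homogeneous nitrate grid, read-out
  after 8 days (192 h).
- **Split root**: n = 2, halves at 25 (LN) or 5000 (HN) μmol/L, both
  starting at 20 mm, read-out after 6 days (144 h). The heterogeneous run
  supplies both LN/HN and HN/LN focal halves; the homogeneous runs supply
  LN/LN and HN/HN. Reported lengths are rounded to integer mm.
- **Patch**: n = 16 equal 20-mm compartments, one at 5000 μmol/L and the
  rest at 25 μmol/L, 144 h (chosen for comparability with the split-root
  runs), comparing CK gating on vs off.
- **Pool initialization**: by default all pools start empty at treatment
  onset (`init_pools="zero"`); `"steady_state"` pre-equilibrates them at
  the frozen initial lengths using the closed-form fixed points. The choice
  matters: the systemic CEP/CK pools degrade at 0.001 h⁻¹ (a ~40-day
  timescale), so within a 6-day run they never equilibrate from zero. With
  empty pools the wild-type split root ends at 36/134 mm (low/high), close
  to the reference 36/128; with pre-equilibrated pools the demand boost is
  active from t = 0 and the high side overshoots to ~193 mm. Zero
  initialization is therefore the default and the documented study
  condition. A corollary: with empty pools the CK gate is still ramping
  during the entire run, so disabling CK gating changes the heterogeneous
  high side by ~12% (134 vs 153 mm) rather than being nearly neutral as it
  is under pre-equilibrated pools (<1%).

## Numerical choices

- Integration: `scipy.integrate.solve_ivp`, LSODA, rtol 1e-8, atol 1e-10,
  sampled hourly (all configurable). Reported 144-h lengths move by far less
  than 0.1 mm when tolerances are tightened tenfold.
- The carbon-allocation growth law is implemented literally as
  dL_x/dt = g_carbon,x·conv·r_x·ΣL, i.e. r_x appears both inside the
  allocation fraction and as the multiplicative rate. An alternative reading
  — g_carbon allocating the sink-weighted total growth conv·Σr_y·L_y — is
  available as `allocation_mode="replace_1_over_n"` but moves the wild-type
  split-root outcome far from the reference table, so the literal form is
  the default.
- Non-negativity: the maintenance term u_m·ΣL is a zeroth-order sink and
  could push the systemic nitrate pool negative when uptake is still
  ramping; the sink is capped at the incoming flux whenever N_s ≤ 0.
  Systemic concentrations clip tiny negative excursions at 0 before
  entering the regulatory functions, and the integrator asserts the state
  never goes materially negative.
- Degenerate allocation: if every r_x·L_x = 0, carbon fractions fall back
  to the uniform 1/n (no growth occurs regardless).
- Concentrations at zero length are unreachable: initial lengths must be
  positive and growth factors are non-negative, so lengths never shrink.

## Limitations

No spatial root architecture, shoot compartment, vacuolar nitrate storage,
soil nitrate dynamics, root:shoot ratio feedback or stochasticity. The model
captures relative growth asymmetries between compartments under constant
external nitrate; absolute lengths inherit the simplifications above, and
quantitative mutant effects are indicative rather than exact. Local CK
concentration is defined (CK_x/L_x) but unused by any regulatory function;
only the systemic CK pool matters.
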