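# Methods

This note records the model, its assumptions, the provenance of every
default parameter, and the numerical choices, in the package's own terms.

## Model structure

Each chamber (anode, cathode) is a continuous stirred-tank reactor with a
liquid phase and a headspace. Differential states per liquid:

- **acid-base family totals** (acetate, butyrate, carbonate, ammonium,
  hypochlorite): the analytical sum over all protonation states;
- **strong ions** (Na+, K+, Cl-, ClO4-, ClO3-, ClO2-): fully dissociated;
- **neutral solutes** (ethanol, butanol, dissolved H2, dissolved CH4);
- **one proton-inventory state `A`**: the net dissociable-proton excess of
  the liquid relative to fully deprotonated reference species
  (`A = [H+] − [OH−] + Σ bound protons`). Electrode H+ turnover, acid-base
  coefficients of every reaction column, and H+/OH− membrane transport all
  act on `A`;
- **biomass** per microbial functional group (mol-C/L of CH1.8O0.5N0.2),
  plus an inert pool fed by first-order decay.

H+, OH− and water are never integrated. pH is an algebraic state recovered
at every right-hand-side evaluation by solving the proton/charge condition —
a single scalar equation in pH, since every equilibrium in the system is a
proton exchange whose mass-action law makes all free concentrations explicit
functions of [H+] given the totals. The solver brackets the root in
pH ∈ [−2, 16] (warm-started to a ±0.05 window between steps) and polishes it
with Brent iteration to machine precision; family equilibria and mass
balances then hold exactly by construction, and the returned charge residual
is below 1e-10 eq/L. Electroneutrality of the *integrated* states is not
imposed; it is an emergent invariant (every reaction column and membrane
flux is charge-consistent) that `System.charge_consistency` audits.

Activity coefficients are unity (ideal dilute solution); no ionic-strength
correction, precipitation or temperature-dependent heat capacities are
modelled. Temperature enters equilibrium constants through the
Gibbs–Helmholtz correction when T ≠ 298.15 K, which requires formation
enthalpies and raises an explicit error if they are missing.

## Thermodynamic layer

All equilibrium constants, reaction Gibbs energies and electrode Nernst
potentials derive from the packaged table of standard Gibbs energies (and
enthalpies) of formation (`src/metsim/data/species.tsv`, cited per row;
mostly Thauer et al. 1977 and CRC values, aqueous standard states). Henry
solubilities for CO2, CH4 and H2 are *derived* from the same table
(`K_H = exp(−(ΔGf,aq − ΔGf,gas)/RT)`) so gas–liquid equilibrium is exactly
consistent with speciation. Notable choice: butanol's aqueous formation
energy uses the CRC liquid value (−162.5 kJ/mol) with no transfer
correction, since 1-butanol's aqueous solubility is close to the 1 M
standard state; this value sets the ethanol:butanol equilibrium manifold of
the MEC case study and is the single most sensitive thermodynamic datum in
it (the product ratio varies as exp(ΔΔG/RT) per 4 electrons, i.e. a factor
e per ~2.5 kJ/mol).

Fermentative rates are multiplied by a smooth feasibility factor
`max(0, 1 − exp((ΔG_r + ΔG_min)/RT))` evaluated on the catabolic
stoichiometry at in-situ free concentrations (ΔG_min = 0 by default). A
smooth switch was chosen over a hard on/off threshold because a
discontinuous right-hand side breaks stiff integration; the factor is ~1
beyond −10 kJ/mol of driving force. Concentrations are floored at
1e-12 mol/L inside logarithms.

## Reaction columns

Every column couples an exactly balanced catabolic stoichiometry with an
exactly balanced anabolic one:

- heterotrophic growth: fraction `f_an` of substrate uptake is anabolised;
  the balancer closes C/H/O/N/charge with biomass, NH4+, CO2, H2O and H+,
  the CO2 term absorbing the redox mismatch between substrate and biomass;
- electrotrophic growth (H2-evolving and perchlorate-reducing biocathodes):
  `Y_electro` mol biomass-C per mol reaction is fixed from CO2 with
  anabolic electrons drawn from the electrode (the column's electron
  coefficient includes them).

Balancing is done in exact rational arithmetic at build time; an unbalanced
column raises naming the element/charge residuals. The electron
pseudo-species carries one electron equivalent, so every balanced column
also conserves COD exactly.

## Electrical model

Given both chambers' states, the cell solve finds the unique pair of
electrode potentials such that (i) per-reaction currents sum to the same
total at both electrodes and (ii) circuit closure holds
(MFC: `E_cat − E_an = I(R_ext + R_int)`; MEC:
`V_app = E_an − E_cat + I(R_ext + R_int)`). Because total anodic current is
monotone increasing in the anode potential and cathodic current monotone
decreasing in the cathode potential, the problem collapses to one scalar
root-find in the anode potential (Brent, 1e-12 V tolerance, warm-started
from the previous accepted step for speed and branch continuity).

Per-reaction currents: `I_j = n_j F rate_j V_liq / 86400` with
`rate_j = k_max X_j · Monod(S_surf) · I_pH · η/(K_SE + η)` and
`η = ±(E_electrode − E_nernst,j)` truncated at zero (no reverse current;
reverse processes are separate reactions). The Nernst–Monod exponential
form `1/(1 + exp(−Fη/RT))` is selectable per reaction. Surface
concentrations come from a steady diffusion-layer balance
`k_m A (S_bulk − S_surf) = consumption`, solved jointly with the rate law
(unique root by monotonicity); the Nernst potential is evaluated at the
surface concentration, so concentration polarization appears through the
equilibrium potential rather than as a separate loss term. Internal
resistance is one lumped ohmic parameter (solution + membrane + contacts).

## Membrane

Ion transport is purely current-coupled: total ionic charge flux equals the
electrical current exactly, partitioned by transport numbers
`t_i ∝ P_i c_i λ_i |z_i|` (relative permeability × source-side
concentration × limiting molar conductivity × charge). Cations are carried
out of the anode, anions out of the cathode. Membrane types: CEM (anions
blocked), AEM (cations blocked), PEM (a CEM whose selectivity favours
H+/OH− over other cations by a factor 1e6 — both case studies use a proton
exchange membrane, and proton transport is what lets the anode export its
oxidation protons and stay near-neutral while the cathode receives them),
or custom per-ion permeabilities. Diffusive crossover of neutral species is
not modelled.

## Gas phase

Headspace partial pressures integrate
`dp/dt = RT(V_liq/V_gas)(q − p·q_vent/(P − P_w))` with `q` the gas–liquid
transfer rates (`kLa (S − K_H p)`) and venting clamped one-way
(`q_vent = max(Σq, 0)`), i.e. an overpressure valve: a net-absorbing liquid
draws the headspace below total pressure instead of sucking gas in (the
symmetric venting term is exponentially unstable under net absorption).
Cumulative vented moles are carried as quadrature states so the
conservation audits and electron-fate bookkeeping are exact. Water vapour
pressure follows the Antoine correlation at the run temperature.

## Parameter provenance (defaults ledger)

`src/metsim/params.py` is the parameter source of record. Microbial
kinetics are ADM1 benchmark values converted to a molar basis (acetate
degraders 4.2 /d with K_S 2.3 mM, butyrate 4.2 /d / 0.8 mM, hydrogenotrophs
73.5 /d / 1 µM; decay 0.02 /d; anabolic fractions 5–10%). Anode-respiring
acetate oxidisers are set 2× faster than aceticlastic methanogens,
consistent with anodes out-competing methanogenesis for acetate. The
electrode-quality constant K_SE (0.26 V) and the lumped internal resistance
(135 Ω) are the electrical model's semi-empirical calibration parameters:
they were set so the MEC base case operates in the regime the case study
describes — ohmic losses absorbing most of the applied voltage at a ~75 mV
electrode-potential difference and a few mA of current. Hydrogen evolution
carries its own much larger K_SE (1.0 V): plain carbon cathodes are poor H2
catalysts, which is what routes cathodic current to VFA reduction. The
butyrate-reduction branch is mildly slower than the acetate branch
(k_max 1.65 vs 4.0, f_an 0.091 vs 0.10), consistent with the observed
acetate-dominated current split.

Media and inocula are part of the experiment definition: the MEC feed is
the stated 0.1 M acetic + 0.1 M butyric acid, fed as a ~50%-neutralised
Na+/NH4+ growth medium (feed pH ≈ 4.9) — the cation load carries residual
membrane current while the free acid supplies the cathodic proton demand.
The anode starts on working digestate liquor with a digester sludge + anode
film inoculum; the cathode on fresh acidified medium with an
electrode-enriched culture (trace initial products seed the product
equilibria). The MFC case converts the stated 350 mg/L acetate and
perchlorate feeds to molar units (5.93 mM, 3.52 mM) in near-neutral salt
media with bicarbonate as the biocathode's carbon source.

Both chambers of a case share geometry (0.2 L liquid, 0.05 L gas, 0.01 m²
electrode and membrane area); biomass is retained with SRT 50 d (MEC) /
25 d (MFC) under a 0.1 mol-C/L crowding cap.

## Numerical choices

- Stiff integration: BDF; the spec-level default tolerances are
  rtol 1e-8 / atol 1e-12; the shipped study configurations use rtol 1e-7 /
  atol 1e-10, which the conservation audits show is ample (elements
  conserved to <1e-6 relative over 100 days).
- Steady state: integrate in chunks until
  `max |dX/dt| / max(|X|, floor) < tol`. Default criterion 1e-6/d with a
  1e-9 floor; the study configurations use 1e-3/d with a 1e-6 floor and a
  400-day horizon, because the strict criterion is dominated by the
  biologically irrelevant exponential tail of extinct populations.
- Sweeps warm-start each point from the previous steady state
  (continuation) and report failed points as flagged rows.
- Non-negativity is maintained by the dynamics (all rates vanish at zero
  substrate) rather than clipping; rate laws clamp their *inputs* at zero
  so the integrator may probe infinitesimally negative states.
- Degenerate inputs: chambers with no electroactive reactions (or no
  feasible driving force) return an exact zero-current open-circuit
  solution; a chamber with no feed has no washout and no SRT wasting.

## What the shipped configurations do and do not show

The two case studies are *theoretical* designs: their media, inocula and
electrode parameters are the package's documented defaults, not fits to a
physical reactor. Passing tests demonstrate internal consistency (exact
stoichiometry, conservation, the two electrical rules, oracle-verified pH
and current partitioning) and that the configured systems reproduce the
expected qualitative and quantitative operating behaviour of the
corresponding MET designs. They do not validate the kinetic parameters
against any particular experimental dataset, and several emergent features
are sensitive to the medium definition — notably the inter-chamber pH
split, which is bistable: small changes in feed neutralisation can flip the
cathode between an acidic, alcohol-producing regime and an alkaline,
methanogen-dominated one (the feed-ratio sweep crosses exactly this cliff
at high anode fractions, which is also where the original case study
reports unstable responses).

## Known limitations

- No spatially resolved biofilm; retention is a lumped SRT with a crowding
  cap.
- No ionic-strength corrections; unit activity coefficients.
- H and O are exchanged freely with the (unmodelled) solvent reservoir, so
  only C, N, Cl, Na, K are conserved quantities of the state vector.
- Membrane ohmic loss is folded into the lumped internal resistance; the
  transport model carries ions, not voltage. No Donnan potentials or
  electro-osmosis.
- The ethanol:butanol split rides on a neutral equilibrium manifold and
  equilibrates slowly (hundreds of days in the base configuration); its
  steady value is exponentially sensitive to small Gibbs-energy or
  growth-parameter asymmetries between the two reduction branches.
- Identity of the third perchlorate intermediate step is modelled as
  hypochlorite/chloride electron bookkeeping; in real perchlorate respirers
  the final steps run through chlorite dismutation.
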