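# Model notes: the YAP regulation scheme

This file records the exact reaction scheme implemented in
`canaliflow.hippo`, the assumptions behind it, and the places where a
modelling choice had to be made because the mechanism list (synthesis,
degradation, (in)activation, sequestration, shuttling) does not fix the
equations uniquely.

## Species and reactions

Seven species in two compartments (concentrations per compartment):

| symbol | meaning |
|--------|---------|
| S, S_i | active / inactivated mechano-sensor (S + S_i = S_tot) |
| Y_c    | active (nuclear-competent) cytoplasmic YAP |
| Y_i    | inactivated (phosphorylated) cytoplasmic YAP |
| C, SF  | Y_i:SF complex / free sequestration factor (C + SF = SF_tot) |
| Y_n    | nuclear YAP |

    dS/dt   = k_sens_on S_i  -  k_sens_off S h(u)
    dY_c/dt = k_syn + k_react Y_i - V_inact S Y_c/(K_inact + Y_c)
              - k_in Y_c + k_out Y_n (V_nuc/V_cyt)
    dY_i/dt = V_inact S Y_c/(K_inact + Y_c) - (k_react + k_deg) Y_i
              - k_bind Y_i SF + k_unbind C
    dC/dt   = k_bind Y_i SF - k_unbind C
    dY_n/dt = k_in Y_c (V_cyt/V_nuc) - k_out Y_n

with the stimulus-activation function

    h(u) = u^n / (K_sens^n + u^n),      n = sensor_hill >= 1.

The volume factors make amounts (concentration x volume) balance across
the nuclear envelope, so total YAP is conserved when synthesis and
degradation are switched off (verified as a test invariant).

## Cooperative stimulus sensing

With plain Michaelis-Menten sensing (n = 1) the closed-form
quasi-steady-state nuclear-YAP curve is a linear-fractional (Moebius)
function of the stimulus: every stage of the steady-state solution —
h(u), S(h), Y_c(S) — is itself Moebius, and Moebius maps compose to a
Moebius map, which has no interior inflection. A curve of that family
can rise steeply but can never be sigmoidal, and a tangent-at-inflection
threshold does not exist for it.

The observed behaviour of the system is a genuine sigmoid with a flat
pre-activation plateau. The scheme therefore gives the sensor step Hill
cooperativity n = `sensor_hill`, modelling cooperative engagement of a
clustered mechano-sensor (multivalent cortical assemblies respond
cooperatively to tension). n is a structural constant of the scheme,
not one of the 16 model parameters, and is never fitted; n = 1 recovers
the plain Michaelis-Menten scheme exactly. The reference regime uses
n = 4, the smallest integer exponent for which the calibrated curve is
robustly sigmoidal over +-2-fold rate perturbations.

## The 16 parameters

14 kinetic constants plus two measured compartment volumes
(V_cyt : V_nuc = 12, hepatocyte geometry; defaults 4800 and 400 um^3).

Fixed to one (they only set concentration/time units at steady state):
`K_inact`, `S_tot`, `SF_tot`, `k_unbind`, `k_sens_on`. Free (estimated
by fitting): `k_syn`, `k_deg`, `V_inact`, `k_react`, `k_sens_off`,
`K_sens`, `k_bind`, `k_in`, `k_out`. `K_sens` must be free because it
positions the activation switch on the stimulus axis; `k_sens_on` fixes
the sensor-recovery time-scale unit instead.

## Steady-state structure (closed form)

Setting the rhs to zero and using the conservation laws:

    S    = k_sens_on S_tot / (k_sens_on + k_sens_off h(u))
    Y_i  = k_syn / k_deg                       (stimulus-independent)
    C    = SF_tot k_bind Y_i / (k_unbind + k_bind Y_i)   (ditto)
    Y_c  = K_inact F / (V_inact S - F),  F = k_syn (k_react + k_deg)/k_deg
    Y_n  = (k_in/k_out)(V_cyt/V_nuc) Y_c

A steady state exists iff V_inact S(u) > F: the sensor-driven
inactivation capacity must exceed the synthesis throughput, otherwise
active YAP grows without bound. The package flags this case explicitly
(`NoSteadyStateError`; partial stimulus-response curves carry per-point
flags).

Two consequences worth stating plainly:

- The sequestered pool C is constant across stimuli at steady state, so
  sequestration sets the *baseline partitioning* of total YAP (and hence
  how strongly the total-YAP observable responds), while the sigmoid
  itself comes from the sensor cascade working near the inactivation
  balance point.
- Nuclear and cytoplasmic active YAP keep a fixed ratio
  (k_in/k_out)(V_cyt/V_nuc), so the *normalized* nuclear curve does not
  constrain k_in, k_out or k_bind: these rates are structurally
  non-identifiable from normalized steady-state data, and the recovery
  report marks them as such.

## Degradation acts on inactive YAP only

Degrading Y_i (not Y_c or Y_n) keeps the total-YAP pool responsive to
the inactivation flux, which is required for the total-YAP observable to
rise together with nuclear YAP rather than stay constant. This is an
assumption of the scheme; degrading active YAP instead would pin
Y_c = k_syn/k_deg and move the stimulus response into the inactive pool.

## Reference parameter set

`HippoParams.reference()`: k_syn 0.2, k_deg 1.0, k_react 0.1 (so F =
0.22 and k_deg perturbations barely move F), V_inact 2.73, k_sens_off
3.0, K_sens 3.0704, k_bind 10 (two thirds of SF occupied at baseline:
sequestration-dominated cytoplasm), k_in 0.1, k_out 1.2 (baseline
nuclear:cytoplasmic active-YAP concentration ratio 1), sensor_hill 4.
K_sens is calibrated once so that the tangent-at-inflection threshold of
the reference curve sits at 1.75-fold relative tension; everything else
is a round number chosen for the regime, not tuned to data.
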