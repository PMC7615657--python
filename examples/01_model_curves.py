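"""Dose-response curves of the promoter model across element strengths.

Evaluates the normalized transcriptional activity A(E)/Amax of a gene
carrying one hormone response element plus a constitutive element of
strength C_T (enhancer > 1, silencer < 1), and the two response-map
features derived from each curve. The printed table shows the dual
effect of a constitutive enhancer: it raises baseline activity and
lowers both the overall fold change and the delta-ratio, so
high-threshold behavior (large fold change AND large delta-ratio)
requires a silencer.
"""

import numpy as np

from ecdose import (
    DoseResponseProfile,
    PromoterArchitecture,
    ReceptorParams,
    half_activation_dose,
    multi_ere_activity,
    response_features,
)

receptor = ReceptorParams(kappa_R_bar=1.0, K_E=65.0)
doses = np.array([0.0, 20.0, 200.0, 2000.0])

print("C_T      A(0)   A(20)  A(200) A(2000)  fold    delta  E_half[nM]")
for label, ct in [("5 (enh)", 5.0), ("1 (none)", 1.0), ("0.1 (sil)", 0.1)]:
    arch = PromoterArchitecture(n_ere=1, C_ER=0.1, C_EA=10.0, C_T=ct, kappa_P=0.1)
    curve = np.asarray(multi_ere_activity(doses, arch, receptor))
    f = response_features(DoseResponseProfile(tuple(doses), tuple(curve)))
    e_half = half_activation_dose(arch, receptor)
    print(
        f"{label:<9}"
        + "".join(f"{v:7.3f}" for v in curve)
        + f"  {f.fold_change:6.2f}  {f.delta_ratio:6.2f}  {e_half:8.1f}"
    )

print(
    "\nEach row is one promoter architecture; activity is normalized to its"
    "\nsaturating-hormone value. The enhancer (C_T=5) lifts the baseline,"
    "\ncompresses the fold change and shifts the half-activation dose down;"
    "\nthe silencer (C_T=0.1) does the opposite, emulating high-threshold"
    "\ntarget genes."
)
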