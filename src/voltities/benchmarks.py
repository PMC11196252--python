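"""Experimentally observed reference values for danofloxacin.

These numbers were measured on real instruments (ITIES cell and glassy
carbon electrode) and are shipped purely as documentation benchmarks for
report annotation and comparison.  Nothing in this package computes them,
and nothing should: several (the ~75 mV peak separation, the backward-
current diffusion coefficient) fold in non-idealities such as
uncompensated organic-phase resistance that the reversible simulator
deliberately does not model.
"""

from __future__ import annotations

from types import MappingProxyType

#: observed benchmarks (read-only).  Keys are self-describing; units in
#: the key suffix.
OBSERVED = MappingProxyType(
    {
        # ITIES reversibility study (at 25 mV/s; broadened by organic-phase
        # resistance relative to the ideal reversible ~59 mV)
        "delta_ep_V": 0.075,
        # Randles-Sevcik diffusion coefficients from forward/backward peaks
        "D_aq_to_org_cm2_s": 1.13e-6,
        "D_org_to_aq_cm2_s": 0.14e-6,
        # formal transfer potential and derived lipophilicity constants
        "phi_formal_V": 0.123,
        "logP_water_dce": -2.08,
        "K_D": 600.0,
        # glassy-carbon scan-rate diagnostic (mixed adsorption-diffusion)
        "gce_loglog_slope": 0.40,
        # milk-matrix detection limits
        "milk_ities_lod_uM": 7.32,
        "milk_ities_loq_uM": 24.38,
        "milk_gce_lod_uM": 4.00,
        "milk_gce_loq_uM": 13.32,
    }
)
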