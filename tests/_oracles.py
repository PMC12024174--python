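"""Frozen self-consistency oracle values for generator recovery checks.

Scored Pearson correlation between AUT fluency and SPQ total, computed once
with the package's own generator + scoring path at n=100000 (seed 2024),
with the latent correlation between the aut_fluency and spq_total latents
set to the key and all other latents independent. Monte-Carlo SE ~ 0.003.
The heavy attenuation (scored r ~ 0.13 x latent rho) reflects the count
noise in fluency and the fact that only the social-anxiety items load on
the SPQ-total latent directly.
"""

RECOVERY_ORACLE = {
    -0.4: -0.05032,
    0.0: 0.00159,
    0.3: 0.04059,
    0.55: 0.07287,
}
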