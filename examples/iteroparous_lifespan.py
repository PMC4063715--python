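"""Iteroparous breeding with allometric fertility b(x) = b0 x^alpha.

The allometric exponent alpha plays exactly the role of the semelparous
convexity index: the optimal resource mix has the same closed form.  The
breeding-age density over [0, omega] is exponential in age — uniform when
the net growth of reproductive output matches the fitness, J-shaped (skewed
to older ages) when it exceeds it — and persistence puts a floor on the
maximum lifespan omega.
"""

from stochdemog.two_resource import (
    TwoResourceParams,
    iteroparous_demography,
    iteroparous_fitness_bound,
    iteroparous_optimal_mix,
)

REF = dict(m1=1.0, m2=0.4, s1=1.2, s2=0.4, mu0=0.05, x0=1.0, xm=5.0)

p = TwoResourceParams(**REF, b0=0.3, alpha=0.4, omega=15.0)
mix = iteroparous_optimal_mix(p)
R0, (ages, psi), omega_min, shape = iteroparous_demography(p, mix)

print(f"optimal weight on risky R1 : {mix.u_star:.3f}  ({mix.regime})")
print(f"fitness lambda*            : {mix.lambda_star:.4f} per unit time")
print(f"infinite-lifespan bound    : {iteroparous_fitness_bound(p):.4f} (upper)")
print(f"lifetime reproduction R0   : {R0:.2f} offspring")
print(f"minimum viable lifespan    : {omega_min:.2f} time units (R0 = 1 there)")
print(f"breeding-age density shape : {shape}")
print()
print("The fitness grows with omega, so selection favors longevity; the")
print(f"density is '{shape}', i.e. "
      + ("older individuals dominate reproduction."
         if shape == "increasing" else
         "reproduction is spread across ages." if shape == "uniform"
         else "young breeders dominate reproduction."))
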