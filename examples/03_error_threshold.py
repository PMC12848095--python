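"""Quasispecies error threshold: missegregation rate flips karyotype dominance.

Builds an engineered two-peak fitness landscape — a single narrow high-fitness
karyotype versus a broad plateau of slightly less fit karyotypes six
missegregations away — and screens the quasispecies steady state across
missegregation rates. Below the critical rate the fittest single karyotype
dominates; above it, mutation pressure pushes the population onto the plateau
whose neighbors remain fit.
"""

from alfak import dominance_screen, two_peak_landscape
from alfak.karyotype import format_karyotype

lut = two_peak_landscape()
rates = [1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1]
screen = dominance_screen(lut, rates)

print("rate        dominant karyotype (chr1..6 copies)   distance to low-rate dominant")
for rate, dom, dist in zip(screen.rates, screen.dominants, screen.distances):
    head = ".".join(str(c) for c in dom[:6])
    print(f"{rate:8.0e}    {head}...                            {dist}")
print()
print("distance 0: the narrow peak (diploid) dominates; a positive distance "
      "marks the error-threshold switch onto the broad plateau")
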