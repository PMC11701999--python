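"""Fractionation-corrected dose: BED conversion and the schedule crossover.

Converts physical doses under the two trial schedules (78 Gy in 39 fractions;
64.6 Gy in 19 fractions) to biologically effective dose, and finds the
alpha/beta at which the two prescriptions are equally potent.
"""

from bedntcp import (
    CF_SCHEME,
    HF_SCHEME,
    RadiobiologyParams,
    alpha_beta_crossover,
    physical_to_bed,
)

for ab in (2.0, 3.0):
    rb = RadiobiologyParams(ab)
    print(f"alpha/beta = {ab:g} Gy")
    for dose in (70.0, 75.0, 78.0):
        print(f"  {dose:5.1f} Gy physical (39 fx) -> {physical_to_bed(dose, CF_SCHEME, rb):6.1f} Gy BED")
    print(f"  CF prescription BED {physical_to_bed(78.0, CF_SCHEME, rb):6.1f} Gy "
          f"vs HF {physical_to_bed(64.6, HF_SCHEME, rb):6.1f} Gy")

x = alpha_beta_crossover(CF_SCHEME, HF_SCHEME)
print(f"\nPrescription BEDs coincide at alpha/beta = {x:.1f} Gy:")
print("below this value the hypofractionated arm delivers the higher BED, above it the lower.")
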