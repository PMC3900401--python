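"""Shared physical/chemical constants.

Monoisotopic mass shifts are kept to 4 decimal places; everything that
does m/z bookkeeping imports from here so a convention change is a
one-line edit.
"""

#: Mass of a proton, Da (charge carrier for positive-mode ions).
PROTON_MASS_DA = 1.00728

#: Monoisotopic +O shift of hydroxyproline / hydroxylysine, Da.
OXYGEN_SHIFT_DA = 15.9949

#: Monoisotopic shift of galactosyl-hydroxylysine, Da.
GAL_SHIFT_DA = 162.0528

#: Monoisotopic shift of glucosylgalactosyl-hydroxylysine, Da.
GLCGAL_SHIFT_DA = 324.1056

#: Standard 20-letter amino-acid alphabet (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Gap symbol in alignments.
GAP = "-"
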