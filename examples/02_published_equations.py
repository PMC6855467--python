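"""Evaluate the published compact LFL/UFL equations.

The compact estimators take a handful of named molecular descriptors
(computed externally, e.g. with Dragon) and return flammability limits in
volume percent.  Shown here on hand-picked descriptor vectors, including
the analytic anchor points used in the tests.
"""

from flamqspr import (
    LflDescriptorVector,
    UflDescriptorVector,
    lfl_eq12,
    ufl_eq13,
)

# anchor points: all-zero descriptors isolate the constant structure
print("LFL at zero descriptors :", lfl_eq12(LflDescriptorVector(0, 0, 0, 0)))
print("UFL at zero descriptors :", ufl_eq13(UflDescriptorVector(0, 0, 0, 0, 0)))

# unit descriptors exercise every term of the LFL equation
ones = LflDescriptorVector(SIC0=1, AAC=1, PW5=1, GATS1v=1)
print("LFL at unit descriptors :", lfl_eq12(ones))

# an arbitrary order-unity descriptor vector, to show a general evaluation;
# meaningful LFL estimates require descriptors of a real molecule computed
# by descriptor software, inside the equation's training domain
d = LflDescriptorVector(SIC0=0.62, AAC=1.10, PW5=0.45, GATS1v=1.05)
print(f"LFL(SIC0={d.SIC0}, AAC={d.AAC}, PW5={d.PW5}, GATS1v={d.GATS1v})"
      f" = {lfl_eq12(d):.3f} vol %")

# The zero point of the UFL equation returns its 14.011 intercept; the LFL
# equation has no constant term, so it vanishes at the origin.  The 11-term
# LFL polynomial is steep: off-domain inputs extrapolate freely.
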