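"""Build the sRGB calibration reference from chart patch reflectance spectra.

The nine chart patches are measured with a D50/2-degree spectrocolorimeter
before deployment.  Integrating each reflectance spectrum against the
illuminant and the CIE 1931 2-degree observer, adapting to D65 and encoding
as sRGB gives the fixed target color every frame is calibrated onto.
"""

from reefwatch.synthetic import chart_reflectance_spectra, default_patch_layout
from reefwatch import build_chart_reference

spectra = chart_reflectance_spectra()  # stand-in for the measured spectra
chart = build_chart_reference(spectra, default_patch_layout())

print("patch  reference sRGB")
for patch in chart.patches:
    print(f"  {patch.patch_id}    {patch.srgb}")
# Each row is the 8-bit color the corresponding patch should have in a
# perfectly calibrated frame; patches 1-3 are a neutral ramp (R=G=B).
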