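"""Internal-standard calibration, concentration and odor activity value.

Fits a 1/x-weighted calibration curve, converts a response ratio into a
concentration, and expresses it in odor threshold units (OAV).
"""

from vinomix.quantify import compute_oav, fit_calibration, predict_concentration, semi_quantify

# five-level calibration series (conc ug/L, analyte/IS response ratio)
levels = [(99.0, 0.199), (247.5, 0.496), (495.0, 0.991), (990.0, 1.982), (1980.0, 3.961)]
curve = fit_calibration(levels, compound="Isoamyl acetate")
print(f"calibration: slope {curve.slope:.5f}, intercept {curve.intercept:.4f}, "
      f"weighted r2 {curve.r2:.5f} ({'usable' if curve.usable else 'flagged'})")

ratio = 0.991  # measured analyte area / 2-octanol area in a wine sample
conc, flags = predict_concentration(curve, ratio)
oav = compute_oav(conc, odor_threshold=30.0)
print(f"response ratio {ratio} -> {conc:.1f} ug/L; OAV = {oav:.1f} (threshold 30 ug/L)")
print("-> an OAV far above 1 marks this banana-like ester as a driver of the")
print("   wine's aroma, which is why OAV ranks compounds for standard purchase.")

semi = semi_quantify(0.30, is_conc=50.0)
print(f"no authentic standard? semi-quantitation: ratio 0.30 -> {semi:.0f} ug/L "
      f"(2-octanol equivalents, response factor 1)")
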