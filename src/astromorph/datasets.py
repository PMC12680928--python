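"""Small reference tables used by the worked examples.

``MICRODIALYSIS_MEANS_MM`` holds published group-mean extracellular amino-acid
concentrations (mM) from cortical microdialysis of control (CTR) and
astrocyte-specific Tcf7l2 knockout (cKO) mice, at baseline and 40 min after a
50 mM potassium pulse. They are the canonical inputs for the percent-change
reporting utilities.
"""

MICRODIALYSIS_MEANS_MM = {
    "glutamate": {"ctr": 0.060, "cko": 0.127},
    "glutamine": {"ctr": 2.99, "cko": 5.16},
    "taurine": {"ctr": 0.52, "cko": 0.72},
    "glutamine_post_k": {"ctr": 3.03, "cko": 5.41},
    "alanine_post_k": {"ctr": 0.73, "cko": 1.04},
}

# I-V protocol of the patch-clamp recordings the Hill fit serves: current
# steps in 20 pA increments from -200 to 1000 pA.
IV_STEPS_PA = list(range(-200, 1001, 20))
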