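{
    "comment": "Biexponential population arterial input function constants (Weinmann/Tofts-Kermode form). Amplitudes in kg/L, decay rates in 1/min; blood concentration is dose * (a1*exp(-m1*t) + a2*exp(-m2*t)).",
    "a1": 3.99,
    "a2": 4.78,
    "m1": 0.144,
    "m2": 0.0111,
    "hct": 0.45,
    "dose_mmol_per_kg": 0.1
}
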