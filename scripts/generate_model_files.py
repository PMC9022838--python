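"""Regenerate the shipped TCA-cycle model files and manifest.

Writes src/fluxsel/models/{m1..m7}.tsv, tracers.csv and manifest.json.
The seven models are nested: each adds exactly one reaction to the
previous one, so free-flux counts increase strictly by one.
"""

import csv
import json
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "src" / "fluxsel" / "models"

HEADER = [
    "#substrate PYR.ext GLN.ext CO2.in AC.unl",
    "#sink CO2",
    "#measured PYR CIT ACON AKG GLU GLN FUM MAL ASP",
    "reaction_id\tequation\treversible\tnotes",
]

CORE = [
    ("PYRT", "PYR.ext(abc) -> PYR(abc)", "pyruvate uptake (normalized to 1)"),
    ("GLNT", "GLN.ext(abcde) -> GLN(abcde)", "glutamine uptake"),
    ("PDH", "PYR(abc) -> ACCOA(bc) + CO2(a)", "pyruvate dehydrogenase"),
    ("CS", "ACCOA(ab) + OAA(cdef) -> CIT(fedcba)", "citrate synthase"),
    ("ACONT1m", "CIT(abcdef) -> ACON(abcdef)", "aconitase, citrate -> cis-aconitate"),
    ("ACONT2m_IDH", "ACON(abcdef) -> AKG(abcde) + CO2(f)",
     "cis-aconitate -> isocitrate -> AKG (lumped)"),
    ("GLS", "GLN(abcde) -> GLU(abcde)", "glutaminase"),
    ("GDH", "GLU(abcde) -> AKG(abcde)", "glutamate dehydrogenase"),
    ("OGDH", "AKG(abcde) -> 0.5 FUM(bcde) + 0.5 FUM(edcb) + CO2(a)",
     "AKG -> succinate -> fumarate (lumped, symmetric scrambling)"),
    ("FUMm", "FUM(abcd) -> 0.5 MAL(abcd) + 0.5 MAL(dcba)",
     "fumarase (symmetric substrate)"),
    ("MDH", "MAL(abcd) -> OAA(abcd)", "malate dehydrogenase"),
    ("GOT", "OAA(abcd) -> ASP(abcd)", "aspartate transaminase"),
    ("ASCm", "ACCOA(ab) -> AC(ab)", "acetyl-CoA hydrolysis / acetate release"),
    ("PYR_ef", "PYR ->", "efflux"),
    ("CIT_ef", "CIT ->", "efflux"),
    ("ACON_ef", "ACON ->", "efflux"),
    ("AKG_ef", "AKG ->", "efflux"),
    ("GLU_ef", "GLU ->", "efflux"),
    ("GLN_ef", "GLN ->", "efflux"),
    ("FUM_ef", "FUM ->", "efflux"),
    ("MAL_ef", "MAL ->", "efflux"),
    ("ASP_ef", "ASP ->", "efflux"),
    ("AC_ef", "AC ->", "efflux"),
]

ADDITIONS = [
    ("m2", "GDH_rev", "AKG(abcde) -> GLU(abcde)",
     "reverse glutamate dehydrogenase (labels glutamate from the TCA cycle)"),
    ("m3", "GLNS", "GLU(abcde) -> GLN(abcde)", "glutamine synthetase"),
    ("m4", "ME", "MAL(abcd) -> PYR(abc) + CO2(d)", "malic enzyme"),
    ("m5", "ME_rev", "PYR(abc) + CO2.in(d) -> MAL(abcd)",
     "reductive carboxylation of pyruvate to malate (malic enzyme, reverse)"),
    ("m6", "PC", "PYR(abc) + CO2.in(d) -> OAA(abcd)", "pyruvate carboxylase"),
    ("m7", "ACE", "AC.unl(ab) -> ACCOA(ab)", "unlabeled acetyl entry into acetyl-CoA"),
]

# Feasible true flux vector for the generating model M4 (pyruvate uptake = 1);
# every M4 reaction carries nonzero flux and all balances close.
TRUE_FLUXES_M4 = {
    "PYRT": 1.0, "GLNT": 0.85, "PDH": 0.80, "CS": 0.70, "ACONT1m": 0.65,
    "ACONT2m_IDH": 0.60, "GLS": 0.85, "GDH": 0.85, "OGDH": 1.15, "FUMm": 1.10,
    "MDH": 0.90, "GOT": 0.20, "ASCm": 0.10,
    "GDH_rev": 0.20, "GLNS": 0.10, "ME": 0.15,
    "PYR_ef": 0.35, "CIT_ef": 0.05, "ACON_ef": 0.05, "AKG_ef": 0.10,
    "GLU_ef": 0.10, "GLN_ef": 0.10, "FUM_ef": 0.05, "MAL_ef": 0.05,
    "ASP_ef": 0.20, "AC_ef": 0.10,
}

TRACERS = [
    ("U-13C-pyruvate", "PYR.ext", "111"),
    ("U-13C-glutamine", "GLN.ext", "11111"),
    ("3-13C-pyruvate", "PYR.ext", "001"),
    ("1,2-13C-glutamine", "GLN.ext", "11000"),
]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = list(CORE)
    diff = {"m1": [r[0] for r in CORE]}
    for i, (mid, rid, eq, note) in enumerate(ADDITIONS, start=2):
        rows = rows + [(rid, eq, note)]
        diff[f"m{i}"] = [rid]
        text = "\n".join(HEADER + [f"{r}\t{e}\t0\t{n}" for r, e, n in rows]) + "\n"
        # also write all smaller models on the way
    # write each model file
    acc = list(CORE)
    for i in range(1, 8):
        if i >= 2:
            mid, rid, eq, note = ADDITIONS[i - 2]
            acc = acc + [(rid, eq, note)]
        text = "\n".join(HEADER + [f"{r}\t{e}\t0\t{n}" for r, e, n in acc]) + "\n"
        (OUT / f"m{i}.tsv").write_text(text)
    with open(OUT / "tracers.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "metabolite", "pattern"])
        for name, met, pat in TRACERS:
            writer.writerow([name, met, pat])
    manifest = {
        "family": "tca",
        "models": [f"m{i}" for i in range(1, 8)],
        "true_model": "m4",
        "true_fluxes_m4": TRUE_FLUXES_M4,
        "normalized_flux": "PYRT",
        "additions": {m: [r] for m, (r, _, _) in
                      zip([f"m{i}" for i in range(2, 8)],
                          [(r, e, n) for _, r, e, n in ADDITIONS])},
        "estimation_tracers": ["U-13C-glutamine", "3-13C-pyruvate",
                               "1,2-13C-glutamine"],
        "validation_tracer": "U-13C-pyruvate",
        "true_polynomial_coefficients": [-0.3, -5.6, 0.8, 44.8, 0.0, -89.6, 0.0, 51.2],
        "true_linear_parameters": [10.0, 5.0, 2.0],
    }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
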