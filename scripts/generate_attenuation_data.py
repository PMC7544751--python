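"""Generate the frozen photon-interaction data module.

Builds per-material mass-interaction-coefficient tables on a fixed energy
grid (10 keV - 1 MeV):

  * total (without coherent): embedded reference mass attenuation values
  * incoherent: Klein-Nishina total cross-section x electrons per gram
  * photoelectric: residual total - incoherent (clamped positive)
  * coherent: approximate embedded channel (off by default in transport)
  * mu_en: photoelectric + incoherent x KN mean energy-transfer fraction

The output is written to src/handdose/_attenuation_data.py and committed;
Run only to regenerate the committed constants module.
"""

import numpy as np
from scipy import integrate

ME = 0.51099895  # MeV
RE = 2.8179403262e-13  # cm
NA = 6.02214076e23

# Z, A for elements used in the material compositions
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "P": (15, 30.974),
    "S": (16, 32.06), "Cl": (17, 35.45), "Ar": (18, 39.948),
    "K": (19, 39.098), "Ca": (20, 40.078), "Fe": (26, 55.845),
    "Zn": (30, 65.38), "W": (74, 183.84),
}

MATERIALS = {
    "air": {
        "density": 1.20479e-3,
        "composition": {"C": 0.000124, "N": 0.755268, "O": 0.231781,
                        "Ar": 0.012827},
    },
    "water": {
        "density": 1.0,
        "composition": {"H": 0.111894, "O": 0.888106},
    },
    "soft_tissue": {
        # ICRP skin composition, density 1.09 g/cm3
        "density": 1.09,
        "composition": {"H": 0.100588, "C": 0.228250, "N": 0.046420,
                        "O": 0.619002, "Na": 0.000070, "Mg": 0.000060,
                        "P": 0.000330, "S": 0.001590, "Cl": 0.002670,
                        "K": 0.000850, "Ca": 0.000150, "Fe": 0.000010,
                        "Zn": 0.000010},
    },
    "tungsten": {
        "density": 19.3,
        "composition": {"W": 1.0},
    },
}

# Energy grid (MeV) and reference total mass attenuation WITHOUT coherent
# scattering (cm^2/g), standard reference tabulation values.
GRID = np.array([0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080,
                 0.100, 0.150, 0.200, 0.300, 0.400, 0.500, 0.600, 0.800,
                 1.000])

TOTAL_WO_COH = {
    "water": np.array([5.22, 1.58, 0.751, 0.335, 0.243, 0.208, 0.192,
                       0.1748, 0.1641, 0.1460, 0.1335, 0.1165, 0.1045,
                       0.0966, 0.0894, 0.0785, 0.0707]),
    "air": np.array([5.02, 1.53, 0.721, 0.318, 0.225, 0.192, 0.177,
                     0.1585, 0.1481, 0.1316, 0.1203, 0.1050, 0.0942,
                     0.0864, 0.0804, 0.0706, 0.0636]),
    # tungsten includes L edges (10-12 keV) and the K edge (69.5 keV)
    # between grid nodes; interpolation smooths across them.
    "tungsten": np.array([96.91, 139.0, 65.73, 22.73, 10.67, 5.949, 3.713,
                          7.810, 4.438, 1.581, 0.7844, 0.3238, 0.1925,
                          0.1378, 0.1093, 0.08066, 0.06618]),
}
# soft tissue: water scaled (composition slightly less hydrogenous)
TISSUE_SCALE = np.array([0.965, 0.965, 0.967, 0.972, 0.978, 0.982, 0.984,
                         0.988, 0.989, 0.990, 0.990, 0.990, 0.990, 0.990,
                         0.990, 0.990, 0.990])
TOTAL_WO_COH["soft_tissue"] = TOTAL_WO_COH["water"] * TISSUE_SCALE

# Approximate coherent (Rayleigh) channel for water, scaled per material
# by effective Z^2/A; disabled by default in transport.
WATER_COH = np.array([0.115, 0.065, 0.042, 0.021, 0.0125, 0.0085, 0.0060,
                      0.0036, 0.0024, 0.0011, 0.00066, 0.00031, 0.00018,
                      0.00012, 8.6e-5, 5.0e-5, 3.3e-5])


def z_over_a(comp):
    return sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in comp.items())


def z2_over_a(comp):
    return sum(w * ELEMENTS[el][0] ** 2 / ELEMENTS[el][1]
               for el, w in comp.items())


def kn_sigma_total(e_mev):
    """KN total cross-section per electron, cm^2 (closed form)."""
    k = e_mev / ME
    t = 1.0 + 2.0 * k
    s = (1 + k) / k**2 * (2 * (1 + k) / t - np.log(t) / k)
    s += np.log(t) / (2 * k) - (1 + 3 * k) / t**2
    return 2 * np.pi * RE**2 * s


def kn_mean_scatter_fraction(e_mev):
    """<E'/E> over the KN angular distribution (numeric quadrature)."""
    k = e_mev / ME

    def dsig(c):
        r = 1.0 / (1.0 + k * (1.0 - c))
        return r * r * (r + 1.0 / r - (1.0 - c * c))

    num = integrate.quad(lambda c: dsig(c) / (1 + k * (1 - c)), -1, 1)[0]
    den = integrate.quad(dsig, -1, 1)[0]
    return num / den


def main():
    lines = []
    lines.append('"""Frozen photon mass-interaction coefficients (cm^2/g).')
    lines.append("")
    lines.append("Fixed 10 keV - 1 MeV grid. Channels: photoelectric,")
    lines.append("incoherent (Compton), coherent (Rayleigh), total without")
    lines.append("coherent, and mass energy-absorption. Generated file; do")
    lines.append("not edit by hand.")
    lines.append('"""')
    lines.append("")
    lines.append("import numpy as np")
    lines.append("")
    lines.append("ENERGY_GRID_MEV = np.array(%s)" % np.array2string(
        GRID, separator=", ", precision=4,
        formatter={"float_kind": lambda v: "%.4g" % v}))
    lines.append("")
    lines.append("DENSITIES_G_CM3 = {")
    for name, m in MATERIALS.items():
        lines.append('    "%s": %r,' % (name, m["density"]))
    lines.append("}")
    lines.append("")
    lines.append("COMPOSITIONS = {")
    for name, m in MATERIALS.items():
        total = sum(m["composition"].values())
        comp = {el: w / total for el, w in m["composition"].items()}
        items = ", ".join('"%s": %.6f' % (el, w) for el, w in comp.items())
        lines.append('    "%s": {%s},' % (name, items))
    lines.append("}")
    lines.append("")

    zaw = z2_over_a(MATERIALS["water"]["composition"])
    fr = np.array([kn_mean_scatter_fraction(e) for e in GRID])
    sig = np.array([kn_sigma_total(e) for e in GRID])

    def fmt(arr):
        return np.array2string(
            np.asarray(arr), separator=", ", max_line_width=72,
            formatter={"float_kind": lambda v: "%.5g" % v})

    lines.append("TABLES = {")
    for name, m in MATERIALS.items():
        za = z_over_a(m["composition"])
        incoh = NA * za * sig
        total = TOTAL_WO_COH[name].copy()
        pe = total - incoh
        pe = np.maximum(pe, 1e-4 * total)
        total = pe + incoh  # keep channel sum exact
        coh = WATER_COH * (z2_over_a(m["composition"]) / zaw)
        mu_en = pe + incoh * (1.0 - fr)
        lines.append('    "%s": {' % name)
        lines.append('        "photoelectric": np.array(%s),' % fmt(pe))
        lines.append('        "incoherent": np.array(%s),' % fmt(incoh))
        lines.append('        "coherent": np.array(%s),' % fmt(coh))
        lines.append('        "total": np.array(%s),' % fmt(total))
        lines.append('        "mu_en": np.array(%s),' % fmt(mu_en))
        lines.append("    },")
    lines.append("}")
    lines.append("")

    out = "/root/pkg/src/handdose/_attenuation_data.py"
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    print("wrote", out)
    # sanity
    for name in MATERIALS:
        za = z_over_a(MATERIALS[name]["composition"])
        print(name, "Z/A=%.4f" % za)
    k511 = np.exp(np.interp(np.log(0.511), np.log(GRID),
                            np.log(TOTAL_WO_COH["tungsten"])))
    print("W mu/rho @511keV = %.4f -> mu = %.3f /cm" % (k511, k511 * 19.3))


if __name__ == "__main__":
    main()
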