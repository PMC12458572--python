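"""Regenerate the shipped basis data files.

Produces, under src/lobehf/data/:

* ``sto6g_synthetic.gbs`` -- the STO-6G-style reference basis (six-Gaussian
  least-squares refit of Slater orbitals with the standard minimal-basis
  exponents), in Basis Set Exchange Gaussian dialect.  The file is synthetic:
  it is generated by this script, not downloaded.
* ``lobe_basis_cache.json`` -- the fitted lobe expansions (3 Gaussians per s
  shell, 3 mirror pairs per p shell) and the sign-definite per-lobe
  representations used for relevance screening, fitted on the default cube
  grid (half-width 8 Bohr, spacing 0.2 Bohr).

Both fits are deterministic; rerunning this script reproduces the files
bitwise.  Runtime is a few minutes (dominated by the p-shell grid fits).
"""

import pathlib
import sys
import time

from lobehf.basis import FitGrid, build_basis_definition, save_basis_cache
from lobehf.bse import format_basis_text
from lobehf.slater import make_reference_shells

DATA = pathlib.Path(__file__).resolve().parent.parent / "src" / "lobehf" / "data"


def main() -> int:
    t0 = time.time()
    shells = make_reference_shells()
    text = format_basis_text(
        shells,
        comment=(
            "Synthetic STO-6G-style minimal reference basis.\n"
            "Generated by scripts/make_reference_basis.py: six-Gaussian\n"
            "least-squares refit of Slater orbitals (standard minimal-basis\n"
            "zeta values) on a radial grid. Not downloaded data."),
    )
    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "sto6g_synthetic.gbs").write_text(text)
    print(f"wrote sto6g_synthetic.gbs ({time.time() - t0:.1f}s)")

    basis = build_basis_definition(shells, name="lobe-min",
                                   grid=FitGrid())
    for el, shl in basis.shells.items():
        for sh in shl:
            print(f"  {el} {sh.label}: lobe rms {sh.residual_rms:.2e}, "
                  f"abs rms {sh.abs_residual_rms:.2e}")
    save_basis_cache(basis, DATA / "lobe_basis_cache.json")
    print(f"wrote lobe_basis_cache.json ({time.time() - t0:.1f}s)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
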