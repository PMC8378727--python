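"""Partition ruminant excreta carbon into the model's entry pools.

Biodegradability falls exponentially with lignin content, so lignin-rich
excreta route more carbon into the stable HUM/RPM pools and less into the
fast DPM pool.  The shipped default (lignin 18.5 % of volatile solids)
reproduces the 0.1 / 0.6 / 0.3 HUM/RPM/DPM split used for ruminant excreta.
"""

from rothc_grass import EOMQuality, biodegradability, partition_eom
from rothc_grass.eom import DEFAULT_RUMINANT_QUALITY

p = partition_eom(DEFAULT_RUMINANT_QUALITY)
print(f"default ruminant excreta (lignin {DEFAULT_RUMINANT_QUALITY.lignin} % VS):")
print(f"  B = {biodegradability(DEFAULT_RUMINANT_QUALITY.lignin):.3f}")
print(f"  HUM {p.f_hum:.2f}  RPM {p.f_rpm:.2f}  DPM {p.f_dpm:.2f}")

print("\nacross the 9-28 % VS literature interval:")
for lignin in (9.0, 18.5, 28.0):
    rest = (100.0 - lignin) / 2.0
    q = EOMQuality(lignin=lignin, holocellulose=rest, solubles=rest)
    p = partition_eom(q)
    print(
        f"  lignin {lignin:4.1f} %: HUM {p.f_hum:.2f}  RPM {p.f_rpm:.2f}  "
        f"DPM {p.f_dpm:.2f}"
    )
print("more lignin -> lower biodegradability -> more C to the stable pools")
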