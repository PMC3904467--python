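"""Independent month-by-month transcription of the published
Thornthwaite equations, kept separate from the package so it can serve
as an oracle: heat index, cubic exponent, the 26.5 °C high-temperature
polynomial, and the day-length/days-in-month scaling from the
solar-declination sunset-hour-angle formula."""

import math

MONTH_DAYS = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


def independent_thornthwaite(monthly_t, latitude):
    heat = 0.0
    for t in monthly_t:
        if t > 0:
            heat += math.pow(t / 5.0, 1.514)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    pet = []
    doy = 0
    for m in range(12):
        t = monthly_t[m]
        if heat == 0 or t <= 0:
            e = 0.0
        elif t <= 26.5:
            e = 16.0 * math.pow(10.0 * t / heat, a)
        else:
            e = -415.85 + 32.24 * t - 0.43 * t * t
        mid = doy + MONTH_DAYS[m] / 2.0
        decl = 0.409 * math.sin(2.0 * math.pi * mid / 365.0 - 1.39)
        cos_w = -math.tan(math.radians(latitude)) * math.tan(decl)
        cos_w = max(-1.0, min(1.0, cos_w))
        daylight_hours = 24.0 / math.pi * math.acos(cos_w)
        pet.append(e * (daylight_hours / 12.0) * (MONTH_DAYS[m] / 30.0))
        doy += MONTH_DAYS[m]
    return pet
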