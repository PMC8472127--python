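# LDSS slot scanner, chest protocol (speed 6, PA, medium dose).
system_id: LDSS
protocol: chest
tube_voltage_kV: 90
sid_cm: 130
scan_speed: 6
filtration: 0/0.1
beam_mode: slot
sdd_cm: 70
object_plane_offset_cm: 28
# Slot detector pitch is never published; mandatory field, typical slot value.
pixel_pitch_mm: 0.254
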