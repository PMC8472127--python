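# LDSS slot scanner, knee protocol (speed 8, PA, high dose).
system_id: LDSS
protocol: knee
tube_voltage_kV: 68
sid_cm: 130
scan_speed: 8
filtration: 0/0
beam_mode: slot
sdd_cm: 70
object_plane_offset_cm: 20
pixel_pitch_mm: 0.254
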