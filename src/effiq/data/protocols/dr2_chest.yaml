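# DR system 2 flat panel, chest protocol (PA, AEC).
system_id: DR2
protocol: chest
tube_voltage_kV: 145
sid_cm: 300
tube_load_mAs: 1.8
filtration: 0/0.2
beam_mode: cone
sdd_cm: 240
object_plane_offset_cm: 28
pixel_pitch_mm: 0.139
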