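allele	epitope_group	source_version
C*01:02	C1	kirallo-ligand-snapshot-1
C*01:03	C1	kirallo-ligand-snapshot-1
C*03:02	C1	kirallo-ligand-snapshot-1
C*03:03	C1	kirallo-ligand-snapshot-1
C*03:04	C1	kirallo-ligand-snapshot-1
C*07:01	C1	kirallo-ligand-snapshot-1
C*07:02	C1	kirallo-ligand-snapshot-1
C*07:04	C1	kirallo-ligand-snapshot-1
C*08:01	C1	kirallo-ligand-snapshot-1
C*08:02	C1	kirallo-ligand-snapshot-1
C*12:02	C1	kirallo-ligand-snapshot-1
C*12:03	C1	kirallo-ligand-snapshot-1
C*14:02	C1	kirallo-ligand-snapshot-1
C*14:03	C1	kirallo-ligand-snapshot-1
C*16:01	C1	kirallo-ligand-snapshot-1
C*02:02	C2	kirallo-ligand-snapshot-1
C*04:01	C2	kirallo-ligand-snapshot-1
C*04:03	C2	kirallo-ligand-snapshot-1
C*05:01	C2	kirallo-ligand-snapshot-1
C*06:02	C2	kirallo-ligand-snapshot-1
C*15:02	C2	kirallo-ligand-snapshot-1
C*15:05	C2	kirallo-ligand-snapshot-1
C*16:02	C2	kirallo-ligand-snapshot-1
C*17:01	C2	kirallo-ligand-snapshot-1
C*18:01	C2	kirallo-ligand-snapshot-1
B*27:02	Bw4-80I	kirallo-ligand-snapshot-1
B*38:01	Bw4-80I	kirallo-ligand-snapshot-1
B*38:02	Bw4-80I	kirallo-ligand-snapshot-1
B*49:01	Bw4-80I	kirallo-ligand-snapshot-1
B*51:01	Bw4-80I	kirallo-ligand-snapshot-1
B*51:02	Bw4-80I	kirallo-ligand-snapshot-1
B*52:01	Bw4-80I	kirallo-ligand-snapshot-1
B*53:01	Bw4-80I	kirallo-ligand-snapshot-1
B*57:01	Bw4-80I	kirallo-ligand-snapshot-1
B*57:03	Bw4-80I	kirallo-ligand-snapshot-1
B*58:01	Bw4-80I	kirallo-ligand-snapshot-1
B*59:01	Bw4-80I	kirallo-ligand-snapshot-1
B*13:01	Bw4-80T	kirallo-ligand-snapshot-1
B*13:02	Bw4-80T	kirallo-ligand-snapshot-1
B*27:04	Bw4-80T	kirallo-ligand-snapshot-1
B*27:05	Bw4-80T	kirallo-ligand-snapshot-1
B*37:01	Bw4-80T	kirallo-ligand-snapshot-1
B*44:02	Bw4-80T	kirallo-ligand-snapshot-1
B*44:03	Bw4-80T	kirallo-ligand-snapshot-1
B*07:02	Bw6	kirallo-ligand-snapshot-1
B*07:05	Bw6	kirallo-ligand-snapshot-1
B*08:01	Bw6	kirallo-ligand-snapshot-1
B*14:02	Bw6	kirallo-ligand-snapshot-1
B*15:01	Bw6	kirallo-ligand-snapshot-1
B*15:02	Bw6	kirallo-ligand-snapshot-1
B*15:11	Bw6	kirallo-ligand-snapshot-1
B*15:18	Bw6	kirallo-ligand-snapshot-1
B*18:01	Bw6	kirallo-ligand-snapshot-1
B*35:01	Bw6	kirallo-ligand-snapshot-1
B*35:03	Bw6	kirallo-ligand-snapshot-1
B*39:01	Bw6	kirallo-ligand-snapshot-1
B*40:01	Bw6	kirallo-ligand-snapshot-1
B*40:02	Bw6	kirallo-ligand-snapshot-1
B*40:06	Bw6	kirallo-ligand-snapshot-1
B*41:01	Bw6	kirallo-ligand-snapshot-1
B*45:01	Bw6	kirallo-ligand-snapshot-1
B*46:01	Bw6	kirallo-ligand-snapshot-1
B*48:01	Bw6	kirallo-ligand-snapshot-1
B*50:01	Bw6	kirallo-ligand-snapshot-1
B*54:01	Bw6	kirallo-ligand-snapshot-1
B*55:01	Bw6	kirallo-ligand-snapshot-1
B*55:02	Bw6	kirallo-ligand-snapshot-1
B*56:01	Bw6	kirallo-ligand-snapshot-1
B*67:01	Bw6	kirallo-ligand-snapshot-1
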