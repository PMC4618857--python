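# Bowtie2 parameter-optimization scenario: the default setting, the eight
# preset modes, and a grid over seed length (-L), extension effort (-D), and
# re-seeding count (-R) — 9 + 5*5*1 = 34 parameter combinations in total.
mappers:
  - name: bowtie2
    map_command: "bowtie2 -x {reference} -U {fastq1} -S {output} {params}"
    index_command: "bowtie2-build {reference} {reference}"
    sets:
      - {label: default, args: ""}
      - {label: very-fast, args: "--very-fast"}
      - {label: fast, args: "--fast"}
      - {label: sensitive, args: "--sensitive"}
      - {label: very-sensitive, args: "--very-sensitive"}
      - {label: very-fast-local, args: "--very-fast-local"}
      - {label: fast-local, args: "--fast-local"}
      - {label: sensitive-local, args: "--sensitive-local"}
      - {label: very-sensitive-local, args: "--very-sensitive-local"}
    grid:
      "-L": [18, 20, 22, 25, 31]
      "-D": [10, 15, 20, 25, 30]
      "-R": [3]
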