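locus	gene_name
Solyc08g008050.2	SlPIP1;1
Solyc01g094690.2	SlPIP1;2
Solyc12g056220.1	SlPIP1;3
Solyc08g081190.2	SlPIP1;5
Solyc03g096290.2	SlPIP1;7
Solyc09g007770.2	SlPIP2;1
Solyc06g011350.2	SlPIP2;4
Solyc10g084120.1	SlPIP2;5
Solyc11g069430.1	SlPIP2;6
Solyc01g111660.2	SlPIP2;8
Solyc10g055630.1	SlPIP2;9
Solyc09g007760.2	SlPIP2;10
Solyc02g083510.2	SlPIP2;11
Solyc05g055990.2	SlPIP2;12
Solyc06g074820.2	SlTIP1;1
Solyc06g075650.2	SlTIP1;2
Solyc10g083880.1	SlTIP1;3
Solyc12g044330.1	SlTIP2;1
Solyc03g120470.2	SlTIP2;2
Solyc06g060760.2	SlTIP2;3
Solyc06g066560.1	SlTIP2;5
Solyc06g072130.2	SlTIP3;1
Solyc03g019820.2	SlTIP3;2
Solyc08g066840.2	SlTIP4;1
Solyc03g093230.2	SlTIP5;1
Solyc03g005980.2	SlNIP1;1
Solyc02g071920.2	SlNIP1;2
Solyc03g013340.2	SlNIP2;1
Solyc02g071910.1	SlNIP2;2
Solyc06g073590.2	SlNIP3;1
Solyc12g057050.1	SlNIP3;2
Solyc02g091420.2	SlNIP4;1
Solyc05g008080.1	SlNIP4;2
Solyc02g063310.2	SlNIP4;3
Solyc08g013730.2	SlNIP5;1
Solyc03g117050.2	SlNIP6;1
Solyc01g079890.2	SlNIP7;1
Solyc12g019690.1	SlSIP1;1
Solyc10g078490.1	SlSIP1;2
Solyc10g078500.1	SlSIP1;3
Solyc01g056720.2	SlSIP2;1
Solyc10g054840.1	SlXIP1;1
Solyc10g054820.1	SlXIP1;2
Solyc10g054810.1	SlXIP1;3
Solyc10g054800.1	SlXIP1;4
Solyc10g054790.1	SlXIP1;5
Solyc01g111010.2	SlXIP1;6
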