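label;n_cases;anastomotic_leak;wound_infection;dvt;return_to_theatre;respiratory;death_30d
Semmens 2000;9673;6.5;8.3;ns;5.0;ns;4.2
Birks 2001;877;3.3;7.2;ns;5.7;ns;4.1
Kable 2002;5432;ns;2.1;0.3;ns;0.2;0.8
Killingback 2002;1418;4.1;2.1;1.1;2.7;6.7;1.6
McGrath 2004-2005;1911;3.0;6.6-9.1;1.0-6.7;ns;1.6;4.0-4.3
Wong 2005;1293;0.5-1.1;4.2-7.8;2.3-3.9;2.7-6.7;ns;1.2-7.7
Gollop 2006;170;3.0;ns;ns;12.0;ns;5.0
Samson 2007;191;4.5;11.0!;ns;7.0;ns;4.0
O'Grady 2007;133;4.7;22.3!;ns;3.0;7.5;0.8
Bowles 2007 pre-audit;500;8.2;ns;ns;12.2;10.7;6.38
Frye 2009;1513;3.8;ns;ns;ns;ns;0.2
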