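<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:simpleType name="vec3">
    <xs:restriction base="xs:string">
      <xs:pattern value="\s*[-+0-9.eE]+\s+[-+0-9.eE]+\s+[-+0-9.eE]+\s*"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:simpleType name="positiveReal">
    <xs:restriction base="xs:double">
      <xs:minExclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:element name="auxinfo">
    <xs:complexType>
      <xs:all>
        <!-- exactly one orientation style (vectors XOR keyword); the XOR is
             enforced by the reader, not expressible in XSD 1.0 -->
        <xs:element name="ap_vector" type="vec3" minOccurs="0"/>
        <xs:element name="lr_vector" type="vec3" minOccurs="0"/>
        <xs:element name="orientation" type="xs:string" minOccurs="0"/>
        <xs:element name="xy_res" type="positiveReal" minOccurs="0"/>
        <xs:element name="z_res" type="positiveReal" minOccurs="0"/>
        <xs:element name="time_res" type="positiveReal" minOccurs="0"/>
        <xs:element name="bit_depth" minOccurs="0">
          <xs:simpleType>
            <xs:restriction base="xs:integer">
              <xs:enumeration value="8"/>
              <xs:enumeration value="16"/>
            </xs:restriction>
          </xs:simpleType>
        </xs:element>
        <xs:element name="channels" type="xs:positiveInteger" minOccurs="0"/>
      </xs:all>
      <xs:attribute name="version" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
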